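# Cefuroxime -- second-generation cephalosporin, renally cleared with a
# contribution of active tubular secretion.
# PROVENANCE: literature-informed approximations assembled for this package.
schema_version: 1
name: cefuroxime
mw: 424.39
compound_class: monoprotic_acid
pka_values: [2.5]
logp: -0.16
fu_plasma: 0.67
bp_ratio: 0.55
vss_obs: 0.19
cl_iv: 8.4
clr: 7.9
kp_method: rodgers_rowland
kp_scalar: null
binding_protein: hsa
notes: >-
  About 28% of renal elimination is active secretion (MRP4 substrate); the
  model lumps renal handling into a single GFR-proportional clearance, a
  stated simplification of this toolkit.
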