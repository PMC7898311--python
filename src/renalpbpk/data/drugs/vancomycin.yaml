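# Vancomycin -- glycopeptide antibiotic, renally cleared.
# PROVENANCE: literature-informed approximations assembled for this package.
schema_version: 1
name: vancomycin
mw: 1449.3
compound_class: monoprotic_base
pka_values: [8.9]
logp: -3.1
fu_plasma: 0.65
bp_ratio: 0.66
vss_obs: 0.50
cl_iv: 5.8
clr: 5.2
kp_method: rodgers_rowland
kp_scalar: null
binding_protein: agp
notes: >-
  Roughly a quarter of filtered drug undergoes tubular reabsorption in vivo;
  the model lumps renal handling into a single GFR-proportional clearance,
  a stated simplification of this toolkit.
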