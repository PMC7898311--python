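# Ceftazidime -- third-generation cephalosporin, near-exclusively renally
# cleared by glomerular filtration.
# PROVENANCE: literature-informed approximations assembled for this package;
# not a transcription of any proprietary or supplementary input set.
schema_version: 1
name: ceftazidime
mw: 546.58
compound_class: monoprotic_acid
pka_values: [2.7]
logp: -1.6
fu_plasma: 0.90
bp_ratio: 0.60
vss_obs: 0.23        # L/kg
cl_iv: 6.9           # L/h, healthy adult reference
clr: 6.2             # L/h
kp_method: rodgers_rowland
kp_scalar: null      # fitted to vss_obs at build time
binding_protein: hsa
notes: >-
  Eliminated almost entirely by passive glomerular filtration; renal
  clearance is modelled as a lumped GFR-proportional term.
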