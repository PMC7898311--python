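# Cefodizime -- third-generation cephalosporin, predominantly renal
# elimination with a substantial (>25%) non-renal route.
# PROVENANCE: literature-informed approximations assembled for this package.
schema_version: 1
name: cefodizime
mw: 584.66
compound_class: monoprotic_acid
pka_values: [3.1]
logp: -0.8
fu_plasma: 0.14
bp_ratio: 0.55
vss_obs: 0.17
cl_iv: 2.9
clr: 2.0
kp_method: rodgers_rowland
kp_scalar: null
binding_protein: hsa
notes: >-
  Highly albumin-bound; about 30% of elimination is non-renal and is held
  constant across renal-function categories.
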