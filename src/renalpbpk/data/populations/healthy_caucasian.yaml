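# Healthy Caucasian adult reference population -- PLACEHOLDER.
# Literature-informed approximation of a healthy Caucasian adult model
# (ages 18-95); intended as the template from which the Caucasian mild
# renal-impairment model is derived by scaling serum creatinine 1.5-fold
# (derive_caucasian_mild).  Replace with a calibrated model for production.
schema_version: 1
name: healthy_caucasian
category: healthy
sex_ratio_f: 0.5
gfr_band: [90, 160]
kidney:
  volume_coeffs: {baseline: 15.4, bw: 2.04, bh: 51.8}
  density_g_L: 1050
sexes:
  male:
    age_range: [18, 95]
    height_age_coeffs: [178.8, -0.06, -0.0002]
    height_residual_sd: 7.0
    weight_height_coeffs: [2.09, 0.013]
    scr_bands:
      - {age_min: 18, age_max: 95, mean: 84, cv: 0.15}
    hematocrit: [43.0, 0.09]
    agp: [0.80, 0.25]
    hsa_coeffs: [46.0, -0.03, -0.05]
  female:
    age_range: [18, 95]
    height_age_coeffs: [165.2, -0.05, -0.0002]
    height_residual_sd: 6.5
    weight_height_coeffs: [1.53, 0.0165]
    scr_bands:
      - {age_min: 18, age_max: 95, mean: 66, cv: 0.15}
    hematocrit: [39.0, 0.09]
    agp: [0.75, 0.25]
    hsa_coeffs: [45.0, -0.03, -0.05]
provenance: >-
  User-replaceable literature-informed placeholder for a healthy Caucasian
  adult system model.
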