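# Healthy Chinese adult reference population -- PLACEHOLDER.
# The proprietary healthy-Chinese system model is not reproducible here;
# demographics mirror the mild renal-impairment cohort (whose blood and
# kidney parameters were adopted unchanged from healthy Chinese adults) and
# serum creatinine uses typical healthy Chinese adult values.  Replace this
# file with a calibrated healthy model for production use.
schema_version: 1
name: healthy_cn
category: healthy
sex_ratio_f: 0.5
gfr_band: [90, 160]
kidney:
  volume_coeffs: {baseline: 15.4, bw: 2.04, bh: 51.8}
  density_g_L: 1050
sexes:
  male:
    age_range: [18, 65]
    height_age_coeffs: [169.83, -0.0891, 0.0005]
    height_residual_sd: 5.58
    weight_height_coeffs: [2.13, 0.0128]
    scr_bands:
      - {age_min: 18, age_max: 65, mean: 78, cv: 0.15}
    hematocrit: [45.3, 0.095]
    agp: [0.638, 0.23]
    hsa_coeffs: [50.34, -0.0575, -0.0738]
  female:
    age_range: [18, 65]
    height_age_coeffs: [155.95, 0.1158, -0.0016]
    height_residual_sd: 4.59
    weight_height_coeffs: [0.93, 0.0198]
    scr_bands:
      - {age_min: 18, age_max: 65, mean: 62, cv: 0.15}
    hematocrit: [40.5, 0.109]
    agp: [0.575, 0.24]
    hsa_coeffs: [49.38, -0.037, 0.1286]
provenance: >-
  User-replaceable placeholder for the healthy Chinese adult system model;
  serum creatinine means are typical healthy adult values, other parameters
  mirror the mild renal-impairment model.
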