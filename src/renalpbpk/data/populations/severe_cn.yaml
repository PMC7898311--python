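# Chinese severe renal impairment (GFR 15-29 mL/min/1.73 m^2).
# Units as in mild_cn.yaml.
schema_version: 1
name: severe_cn
category: severe
sex_ratio_f: 0.42
gfr_band: [15, 29]
kidney:
  volume_coeffs: {baseline: 5.7, bw: 1.04, bh: 29.8}
  density_g_L: 1050
sexes:
  male:
    age_range: [18, 83]
    height_age_coeffs: [176.04, -0.2536, 0.0015]
    height_residual_sd: 5.40
    weight_height_coeffs: [1.72, 0.0146]
    scr_bands:
      - {age_min: 18, age_max: 50, mean: 411, cv: 0.23}
      - {age_min: 50, age_max: 83, mean: 304, cv: 0.24}
    hematocrit: [33.2, 0.065]
    agp: [1.14, 0.35]
    hsa_coeffs: [43.08, -0.0575, -0.0738]
  female:
    age_range: [18, 83]
    height_age_coeffs: [155.86, 0.0672, -0.001]
    height_residual_sd: 4.75
    weight_height_coeffs: [2.10, 0.0122]
    scr_bands:
      - {age_min: 18, age_max: 30, mean: 412, cv: 0.22}
      - {age_min: 30, age_max: 60, mean: 300, cv: 0.23}
      - {age_min: 60, age_max: 83, mean: 229, cv: 0.20}
    hematocrit: [31.3, 0.071]
    agp: [1.03, 0.35]
    hsa_coeffs: [37.8, -0.0575, -0.1286]
provenance: >-
  Recalibrated Chinese severe renal-impairment system model (observed cohort:
  265-266 M / 162 F; the two source tables disagree by one male).
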