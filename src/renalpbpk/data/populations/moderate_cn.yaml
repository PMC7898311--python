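# Chinese moderate renal impairment (GFR 30-59 mL/min/1.73 m^2).
# Units as in mild_cn.yaml.
schema_version: 1
name: moderate_cn
category: moderate
sex_ratio_f: 0.42
gfr_band: [30, 59]
kidney:
  volume_coeffs: {baseline: 8.4, bw: 1.64, bh: 32.8}
  density_g_L: 1050
sexes:
  male:
    age_range: [22, 83]
    height_age_coeffs: [172.56, -0.1205, 0.0003]
    height_residual_sd: 5.44
    weight_height_coeffs: [2.8, 0.0082]
    scr_bands:
      - {age_min: 22, age_max: 50, mean: 200, cv: 0.23}
      - {age_min: 50, age_max: 83, mean: 156, cv: 0.23}
    hematocrit: [39.7, 0.065]
    agp: [0.793, 0.23]
    hsa_coeffs: [47.1, -0.0575, -0.0738]
  female:
    age_range: [22, 83]
    height_age_coeffs: [168.69, -0.4967, 0.0046]
    height_residual_sd: 4.67
    weight_height_coeffs: [2.89, 0.0071]
    scr_bands:
      - {age_min: 22, age_max: 40, mean: 185, cv: 0.22}
      - {age_min: 40, age_max: 60, mean: 150, cv: 0.24}
      - {age_min: 60, age_max: 83, mean: 125, cv: 0.24}
    hematocrit: [36.5, 0.071]
    agp: [0.715, 0.24]
    hsa_coeffs: [44.9, -0.037, -0.1286]
provenance: >-
  Recalibrated Chinese moderate renal-impairment system model (observed
  cohort: 191 M / 85 F).
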