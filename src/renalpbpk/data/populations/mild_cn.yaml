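# Chinese mild renal impairment (GFR 60-89 mL/min/1.73 m^2).
# Covariate equations and distribution parameters of the recalibrated
# Chinese CKD system model; height residual SDs are the observed-cohort
# per-sex SDs.  Units: height cm, weight kg, serum creatinine umol/L,
# hematocrit %, AGP g/L, HSA g/L, kidney volume mL (BH in m).
schema_version: 1
name: mild_cn
category: mild
sex_ratio_f: 0.22
gfr_band: [60, 89]
kidney:
  volume_coeffs: {baseline: 15.4, bw: 2.04, bh: 51.8}
  density_g_L: 1050
sexes:
  male:
    age_range: [18, 69]
    height_age_coeffs: [169.83, -0.0891, 0.0005]
    height_residual_sd: 5.58
    weight_height_coeffs: [2.13, 0.0128]
    scr_bands:
      - {age_min: 18, age_max: 60, mean: 118, cv: 0.13}
      - {age_min: 60, age_max: 69, mean: 95, cv: 0.10}
    hematocrit: [45.3, 0.095]
    agp: [0.638, 0.23]
    hsa_coeffs: [50.34, -0.0575, -0.0738]
  female:
    age_range: [18, 69]
    height_age_coeffs: [155.95, 0.1158, -0.0016]
    height_residual_sd: 4.59
    weight_height_coeffs: [0.93, 0.0198]
    scr_bands:
      - {age_min: 18, age_max: 50, mean: 93, cv: 0.14}
      - {age_min: 50, age_max: 69, mean: 78, cv: 0.23}
    hematocrit: [40.5, 0.109]
    agp: [0.575, 0.24]
    hsa_coeffs: [49.38, -0.037, 0.1286]
provenance: >-
  Recalibrated Chinese mild renal-impairment system model (observed cohort:
  67 M / 21 F).  Weight-height rows are used in the exponential form
  BW = exp(a + b * BH_cm); see docs/methods.md.
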