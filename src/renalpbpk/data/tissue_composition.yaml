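# Adult human tissue composition for tissue:plasma partition prediction.
# Columns per tissue:
#   f_ew / f_iw : extracellular / intracellular water (volume fraction)
#   f_nl / f_np : neutral lipid / neutral phospholipid (volume fraction)
#   ap_mg_g     : acidic phospholipid content (mg/g tissue)
#   alb_ratio   : tissue:plasma albumin concentration ratio
#   lip_ratio   : tissue:plasma lipoprotein concentration ratio
# Values transcribed from the published adult composition tables of the
# mechanistic tissue-partitioning literature (see docs/methods.md).  The
# "rest" compartment carries an average soft-tissue composition.
ph_plasma: 7.4
ph_intracellular: 7.0
ph_blood_cells: 7.22
plasma:
  f_w: 0.945
  f_nl: 0.0023
  f_np: 0.0013
blood_cells:
  f_w: 0.603
  f_nl: 0.0017
  f_np: 0.0029
  ap_mg_g: 0.50
tissues:
  adipose:  {f_ew: 0.135, f_iw: 0.017, f_nl: 0.853,  f_np: 0.0016, ap_mg_g: 0.40, alb_ratio: 0.049, lip_ratio: 0.068}
  bone:     {f_ew: 0.100, f_iw: 0.341, f_nl: 0.017,  f_np: 0.0017, ap_mg_g: 0.67, alb_ratio: 0.100, lip_ratio: 0.050}
  brain:    {f_ew: 0.162, f_iw: 0.620, f_nl: 0.039,  f_np: 0.0015, ap_mg_g: 0.40, alb_ratio: 0.048, lip_ratio: 0.041}
  gut:      {f_ew: 0.282, f_iw: 0.475, f_nl: 0.038,  f_np: 0.0125, ap_mg_g: 2.41, alb_ratio: 0.158, lip_ratio: 0.0141}
  heart:    {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014,  f_np: 0.0111, ap_mg_g: 2.25, alb_ratio: 0.157, lip_ratio: 0.0160}
  kidney:   {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012,  f_np: 0.0242, ap_mg_g: 5.03, alb_ratio: 0.130, lip_ratio: 0.0137}
  liver:    {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014,  f_np: 0.0240, ap_mg_g: 4.56, alb_ratio: 0.086, lip_ratio: 0.0161}
  lung:     {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022,  f_np: 0.0128, ap_mg_g: 3.91, alb_ratio: 0.212, lip_ratio: 0.0168}
  muscle:   {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010,  f_np: 0.0072, ap_mg_g: 1.53, alb_ratio: 0.064, lip_ratio: 0.0059}
  skin:     {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060,  f_np: 0.0044, ap_mg_g: 1.32, alb_ratio: 0.277, lip_ratio: 0.0096}
  spleen:   {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap_mg_g: 3.18, alb_ratio: 0.097, lip_ratio: 0.0207}
  rest:     {f_ew: 0.230, f_iw: 0.490, f_nl: 0.022,  f_np: 0.0100, ap_mg_g: 2.00, alb_ratio: 0.120, lip_ratio: 0.0150}
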