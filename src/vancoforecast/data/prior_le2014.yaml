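# Pediatric vancomycin population prior (one compartment, intermittent IV infusion).
#
# Structural typical-value model transcribed from Le et al. (2014):
#   CL [L/h] = cl_std * WT^wt_exp * (scr_ref / Scr)^scr_exp
#              * (ln(age_days) / age_scale)^age_exp
#   V  [L]   = v_per_kg * WT
# with WT in kg, Scr in mg/dL, age in days.
#
# NOTE: the between-subject variances (omega2) and the residual error below are
# ASSUMED defaults, not transcribed values: they were set once to typical
# pediatric vancomycin magnitudes (CL CV ~30%, V CV ~20%, proportional residual
# CV 15%) and are meant to be overridden from a study-specific config.
model: le2014
theta:
  cl_std: 0.248
  wt_exp: 0.75
  scr_ref: 0.48
  scr_exp: 0.361
  age_scale: 7.8
  age_exp: 0.995
  v_per_kg: 0.636
omega2:
  cl: 0.09
  v: 0.04
sigma:
  prop_cv: 0.15
  add_sd: 0.0
iov2: 0.0
penalty_space: eta
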