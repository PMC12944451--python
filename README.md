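# vancoforecast

Forecasting the next therapeutic-drug-monitoring (TDM) vancomycin
concentration in critically ill children, and measuring how well different
estimation strategies do it.

Vancomycin dosing in pediatric intensive care is guided by AUC-targeted TDM:
one or two blood levels are drawn per dosing interval ("TDM occasion"), the
patient's individual pharmacokinetic (PK) parameters are estimated, and the
next occasion's concentrations are forecast to steer the dose toward a 24-h
AUC of 400–600 mg·h/L.  This package implements, end to end:

* a **one-compartment intermittent-infusion PK engine** with a pediatric
  population prior — typical clearance
  `CL = θ₁·WT^0.75·(0.48/Scr)^θ₂·(ln(age_d)/7.8)^θ₃` and volume
  `V = θ_V·WT`, log-normal between-subject variability
  (θ′ₖ = θₖ·exp(ηₖ), ηₖ ~ N(0, ωₖ²)), and a residual-error model σⱼ;
* the **first-order (Sawchuk–Zaske) two-point method**:
  `kₑ = ln(c₁/c₂)/(t₂−t₁)`, back-extrapolated end-of-infusion peak, and the
  steady-state clearance identity for Vd;
* **MAP-Bayesian estimation** minimizing

  `OBJ = w_data·Σⱼ (Cobs(j) − f(θ,tⱼ))²/σⱼ² + w_prior·Σₖ ηₖ²/ωₖ²`

  in three variants: *conventional* (1, 1), *flattened* (1, flat_coef) with
  flat_coef ∈ {0.005, 0.02, 0.125, 0.2, 0.3, 0.6}, and *weighted-flattened*
  (w, 1−w) with a pluggable per-occasion weight selector (a fixed weight, or
  a retrospective selector that scores candidate weights on how well they
  would have forecast the previous occasion);
* a seeded **virtual-cohort generator** emulating the study conditions
  (median age 2 y, weight 10 kg, Scr 0.34 mg/dL; 60 mg/kg/day q6h with 1-h
  infusions; peak/mid/trough sampling near 2.0/4.7/5.5 h post-dose;
  between-occasion clearance drift; AUC-guided titration);
* **evaluation**: symmetric relative bias and RMSE,

  `rBias = (1/n)·Σᵢ (Cf(i) − Co(i)) / ((Cf(i)+Co(i))/2) · 100%`,
  `rRMSE = sqrt((1/n)·Σᵢ [...]²) · 100%`,

  patient-cluster bootstrap confidence intervals, and a linear mixed-effects
  factor analysis (random intercept per patient, univariable screen at
  p < 0.05, then a multivariable model).

## Worked example

```python
import dataclasses
import vancoforecast as vf
from vancoforecast.cohort import CohortSpec, generate_cohort

spec = dataclasses.replace(CohortSpec(), n_patients=20, seed=7)
ledgers, truth = generate_cohort(spec)
prior = vf.default_prior()
table = vf.run_matrix(
    ledgers, prior, methods=["conventional", "flat_0.125", "weighted", "first_order"]
)
metrics = vf.stratified_metrics(table, n_boot=500, seed=7)
view = metrics[metrics.samples_used.isin(["trough", "two_post_dose"])]
print(view.round(1).to_string(index=False))
```

prints

```
      method  samples_used   n  rbias  rbias_lo  rbias_hi  rrmse  rrmse_lo  rrmse_hi
conventional        trough 120   -9.2     -19.3       1.7   37.6      30.4      44.2
 first_order two_post_dose 108   -6.9     -17.3       2.8   37.4      30.6      44.8
  flat_0.125        trough 120   -6.4     -14.8       4.2   37.0      29.8      44.4
    weighted        trough 120   -8.2     -17.9       2.8   37.5      30.1      44.5
```

Every row is one (method, sample-selection) cell: `rbias` is the mean
symmetric relative deviation between forecast and observed concentrations
(negative = the forecasts run low, here because clearance drifts downward
between occasions), `rrmse` the corresponding root-mean-square, both in %,
with 95% patient-cluster bootstrap intervals.  Flattening the prior
(`flat_0.125`) trusts the patient's own levels more and reduces the bias
relative to conventional MAP.

The same pipeline is available from the shell:

```bash
vancoforecast all --n-patients 20 --seed 7 --out out/
```

which writes `ledger.csv`, `truth.csv`, `forecasts.csv`, `metrics.csv`,
`lme_rbias.csv`, `lme_rrmse.csv` and a summary figure.

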