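# Methods

## Pharmacokinetic model

All concentrations come from the one-compartment model with zero-order
infusion input and first-order elimination.  A dose of amount `D` (mg)
infused over `T` h starting at `s` contributes

```
C(t) = 0                                          t ≤ s
C(t) = (R/CL)(1 − e^{−ke(t−s)})                   s < t ≤ s+T,  R = D/T
C(t) = (R/CL)(1 − e^{−keT}) e^{−ke(t−s−T)}        t > s+T
```

with `ke = CL/V`; doses superpose linearly.  At steady state the 24-h AUC is
`daily dose / CL`, which is what the titration logic uses.

The population prior is the pediatric vancomycin covariate model
`CL [L/h] = 0.248·WT^0.75·(0.48/Scr)^0.361·(ln(age_days)/7.8)^0.995`,
`V [L] = 0.636·WT` (weight in kg, Scr in mg/dL), with log-normal
between-subject variability `θ′ = θ·e^η`, `η ~ N(0, ω²)`.  The shipped
variances (`ω²_CL = 0.09`, `ω²_V = 0.04`, i.e. ≈30% and ≈20% CV) and the
proportional residual CV of 15% are assumed defaults of typical pediatric
vancomycin magnitude, flagged as such in `data/prior_le2014.yaml`; both are
plain config values meant to be replaced by study-specific estimates.
Covariates may vary in time: serum creatinine is a right-continuous step
series, and every typical-value evaluation is indexed by clock time.

## Estimation

**Two-point (first-order) method.**  From two post-infusion levels of one
interval, assumed at steady state: `ke = ln(c1/c2)/(t2−t1)`; the peak is
back-extrapolated to the end of the infusion (a switch keeps the measured
value instead); `CL = D(1−e^{−keT}) / (T·Cmax·(1−e^{−keτ}))`; `Vd = CL/ke`.
A log record is emitted when the elapsed time is under five estimated
half-lives.  Forecasts evaluate the full superposition with the fitted
parameters over the actual future schedule, so mid-course dose changes are
honored exactly rather than through steady-state shortcut formulas.

**MAP estimation.**  The objective is
`w_data·Σ_j (Cobs_j − f(θ(η), t_j))²/σ_j² + w_prior·Σ_k η_k²/ω_k²` with
(1, 1) for the conventional variant, (1, flat_coef) for the flattened one and
(w, 1−w) for the weighted-flattened one.  Because the flattened objective
with coefficient f is exactly (1+f) times the weighted objective at
w = 1/(1+f), the two variants share their minimizer; w = 0.5 reproduces the
conventional argmin.  w = 0 is rejected at validation — the data term would
vanish and the minimizer would trivially be η = 0, which the conventional
variant already covers meaningfully.

Numerical choices:

* Optimization runs in η (log) space, bounded to [−6, 6] per axis, by
  L-BFGS-B with an analytic gradient; convergence at relative objective
  change < 1e−14 or gradient norm < 1e−10.  Starts are η = 0 and ±1 prior SD
  along each axis; among ties (within 1e−8 relative) the smallest ‖η‖ wins —
  maximal shrinkage is the conservative choice.  Non-convergence from every
  start returns the best candidate flagged `converged=False`, never silently.
* The residual sd σ_j is evaluated at the **observed** concentration,
  `σ_j = sqrt((cv·Cobs_j)² + add²)`, giving fixed weights.  The two-term
  objective carries no log-σ likelihood term, so weights tied to the model
  prediction would make overprediction asymptotically cheap (the misfit term
  saturates as f → ∞) and bias every fit upward; fixed weights keep the data
  term a symmetric quadratic.
* The prior penalty defaults to η-space (`Ση²/ω²`), the standard convention
  for log-normal priors; `penalty_space: theta` computes the literal
  typical-value deviation `(1 − e^η)²/ω²` (ω² read as a squared CV) for
  comparison.
* Predictions use the typical values in force at each observation or
  forecast time, with η held fixed — creatinine updates in the lead time move
  the typical values only, dose updates enter the superposition exactly.

**Weight selection.**  The weighted-flattened coefficient is a strategy
interface.  `FixedWeight` returns a constant (default 0.5 ≡ conventional).
`RetrospectiveWeight` needs at least two prior occasions: each candidate
weight w = 1/(1+f), f ∈ {0.005, 0.02, 0.125, 0.2, 0.3, 0.5, 0.6, 0.8, 1.0},
is fitted to occasion i−2 and scored by squared forecast error on occasion
i−1; the best candidate wins, ties going to the smallest weight.  With a
shorter history it falls back to the fixed default (logged).  A learned
selector can be plugged in through the same interface; none is shipped,
since training such a model requires clinical history data.

## Forecast design

Occasions are the half-open dosing intervals `[start, next start)` that
contain at least one sample, indexed chronologically.  Each target occasion
is forecast from the immediately preceding occasion only, for every method ×
sample-selection cell: single peak / mid / trough, the three pairs, and (for
the two-point method) the first two samples in time order regardless of
window label.  Sampling windows are peak = [1, 2] h after the end of the
infusion and trough = [0.5, 1] h before the next dose (closed intervals, peak
taking precedence), everything else mid.  A requested sample type absent from
the preceding occasion skips the task with a log record, mirroring
observational availability.  Lead time is (first target sample − last used
sample)/24 in days, continuous.

## Virtual cohort

The generator emulates the analysis' assumed structure rather than any real
patient records:

* demographics from log-normals matched to median/IQR (log-median = ln m,
  log-SD = (ln q3 − ln q1)/1.349): age 24 [7.2–56.4] months, weight 10
  [7–15] kg, Scr 0.34 [0.22–0.49] mg/dL;
* 60 mg/kg/day q6h, 1-h infusions; first sampled interval at ≥ 24 h; two to
  four (integer-day) gaps between the default three occasions per patient;
  peak/mid/trough drawn per occasion from truncated normals near 2.0 / 4.7 /
  5.5 h post-dose, kept inside their windows;
* between-subject η on CL and V; multiplicative residual error
  `DV = C_true·e^{ε}`, ε ~ N(0, cv²), cv = 0.15;
* between-occasion variability as Brownian motion on ln CL with diffusion
  0.20 per √day — ≈20% CV across a one-day gap — and drift −0.03/day.
  An independent per-occasion multiplier was rejected because it cannot make
  forecast error grow with the gap to the next occasion; a driftless walk
  cannot make every method's bias negative.  Declining clearance over an ICU
  stay (evolving renal function under vancomycin, furosemide and
  vasopressors) is the clinically plausible mechanism for both, and with it
  the method ordering emerges naturally: estimators that trust the patient's
  recent levels more (flattened, weighted, first-order) track the decline and
  are less biased than conventional MAP, which keeps reverting toward the
  static population prior;
* AUC-guided titration: after each occasion a two-point fit of the first two
  measured levels estimates AUC24 = daily dose/CL; outside 400–600 mg·h/L the
  daily dose is rescaled proportionally (scale rounded to a 5% grid, dose
  clamped to 20–100 mg/kg/day), effective two doses later.

Within an occasion the occasion's parameters are applied to the whole dosing
history (the walk is piecewise-constant per occasion); near steady state the
error of that approximation is negligible.  Ground truth (per-occasion CL, V,
η, walk state, and noise-free concentrations) is emitted alongside the noisy
ledger for recovery tests.

What the generator does **not** emulate: real creatinine dynamics (static by
default; the step-series path exists and is tested), assay quantification
limits, missed or irregularly timed samples, co-medication effects, organ
support, or any model misspecification beyond the clearance walk.  Passing
tests therefore show that the estimators behave correctly under the model's
own assumptions and under between-occasion drift — not that the shipped prior
describes any particular clinical population.

## Evaluation

Per-pair symmetric relative deviation `d = 100·(Cf − Co)/((Cf + Co)/2)`,
bounded in (−200, 200); rBias is its mean, rRMSE the root mean square (so
rRMSE ≥ |rBias|).  Confidence intervals resample whole patients with
replacement (percentile cluster bootstrap, default 1000 replicates), which
respects repeated measures; BCa refinements were deliberately left out.  The
factor analysis fits linear mixed-effects models (random intercept per
patient, ML, Wald 95% CIs) for the per-pair signed deviation ("rBias"
outcome) and its absolute value ("rRMSE" outcome) — the per-observation
operationalization of the aggregate metrics — with conventional MAP and the
pooled two-concentration selections as reference levels, a univariable screen
at p < 0.05, and a multivariable model on the survivors.

## Problem sizes

The shipped checks simulate at the scale the design calls for: a 110-patient
cohort (three occasions, nine samples per patient) for the qualitative
pipeline checks; 300 replicate 50-patient cohorts with 400 bootstrap
replicates for the interval-coverage check; 200 simulated datasets
(50 patients × 6 observations) for mixed-effects slope recovery and type-I
error; 100 random regimens for two-point exactness; dense or basin-refined
grid searches as optimizer oracles on 50 toy problems.

## Known limitations

* The prior's variance components are assumed, not estimated; absolute
  rBias/rRMSE magnitudes on simulated cohorts depend on them and on the walk
  parameters, so only orderings and signs are meaningful.
* The retrospective weight selector needs two prior occasions; with the
  default three occasions per patient, only the last occasion of each patient
  exercises genuine selection.
* One forecast pairs one preceding occasion; pooling deeper history is out of
  scope, as are two-compartment kinetics, nonlinear clearance, renal
  replacement therapy and dose-recommendation logic.
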