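# Methods

## The PSSP model

Follow-up is discretized by a grid t₁ < … < t_k placed at the j/k
quantiles (j = 1..k) of the observed event times, so intervals hold
roughly equal numbers of deaths.  The default is k = 10; `choose_time_grid`
can merge extra points (e.g. the horizons at which curves will be read
off) so those predictions come from a fitted grid point rather than from
interpolation across a possibly wide interval.  Duplicate quantiles under
heavily tied event times collapse the grid with a warning.

For interval j = (t_{j−1}, t_j] an L2-regularized logistic model is fit
for the conditional death probability q_j(x).  A patient enters the fit
only if at risk at t_{j−1} *and* their status at t_j is determined (death
by t_j, or follow-up reaching t_j).  Patients censored strictly inside the
interval are dropped from it and from all later intervals; this is
unbiased when censoring is independent of the event within the interval.
Inverse-probability-of-censoring weighting would use those partial
observations but is not implemented.

The predicted curve is S(t_j|x) = ∏_{l≤j} (1 − q_l(x)), anchored at
S(0) = 1, linearly interpolated between grid points and **flat beyond
t_k** — the curve is never extrapolated toward zero, so queries past
follow-up return the last estimated probability.  Monotonicity holds by
construction; no isotonic correction is applied.

Numerical choices:

* Continuous covariates are standardized inside the model (means/SDs
  stored and replayed at prediction); binary 0/1 columns are left alone so
  the ridge penalty treats indicator contrasts on their natural scale.
* Ridge strength α ≥ 0 (0 = unpenalized MLE).  The default `"cv"` picks α
  from {10⁻³, 10⁻², 10⁻¹, 1, 10} by 5-fold cross-validated log-loss summed
  over intervals, with a fixed fold seed, so fitting is deterministic.
* An interval with fewer than 10 usable patients or no events raises an
  error advising a smaller k.  An interval whose labels are constant
  (e.g. the final interval of a fully uncensored cohort, where everyone
  still at risk dies) gets a shrunken intercept-only classifier
  (logit of (d + ½)/(n + 1)) since covariates carry no information there.

## The Cox-KP comparator

Coefficients come from the Cox partial likelihood (Efron tie handling,
via lifelines).  The baseline survival uses the Kalbfleisch–Prentice
discrete self-consistency construction: at each distinct event time the
interval factor αᵢ solves

    Σ_{j∈Dᵢ} e^{ηⱼ} / (1 − αᵢ^{e^{ηⱼ}})  =  Σ_{k∈Rᵢ} e^{ηₖ},

closed-form for a unique death, bisection/Brent on (0,1) under ties
(xtol 10⁻¹⁴); S₀(t) is the product of factors up to t, a step function.
Covariates are centered at training means for numerical stability, and
S(t|x) = S₀(t)^{exp(βᵀ(x−x̄))}.  With β = 0 every factor reduces to
1 − dᵢ/nᵢ, so the whole pipeline collapses to Kaplan–Meier — used as an
exact oracle in the tests (agreement ≤ 10⁻¹⁰).  Because the exponent is
time-constant, Cox-KP curves never cross: the model cannot express a
covariate that matters early but not late.

## Preprocessing and variable selection

Clinical conventions: INR capped at 5, MELD at 40, creatinine set to
4.0 mg/dL when the dialysis flag is set; natural-log companions for INR,
bilirubin and creatinine; variables missing in strictly more than 40% of
rows are dropped; remaining gaps are mean-imputed (mode for
binary/categorical, ties breaking toward the smaller value for
determinism).  Selection is the standard two-stage Cox filter: a
univariate screen retaining Wald p ≤ 0.1, then multivariate backward
elimination removing the single worst variable per refit until all
remaining have p ≤ 0.05.  Both alphas, the caps and the thresholds are
config.  The univariate test is Wald; a likelihood-ratio screen would be
a reasonable alternative.  Categoricals are reference-level dummy coded.
An empty final set is a valid outcome (the harness then falls back to an
intercept-only / population model).

## Evaluation

**Concordance.**  Over comparable pairs (i died, and before j's observed
time), the fraction where the higher risk score belongs to i; score ties
count ½.  Risk scores from curves are 1 − S(t*|x) at a reference horizon
(default 5 years).

**1-calibration (Hosmer–Lemeshow).**  At horizon t, patients censored
before t are excluded; the rest are sorted by predicted death probability
1 − S(t|x) and cut into 10 equal-count groups; the statistic is
Σ (O−E)²/(E(1−E/n_g)) with dof = groups − 2 (development-sample
convention; the external-validation convention dof = groups is config).
Groups with degenerate expected counts merge with a neighbor.  *Known
limitation:* the exclusion rule conditions on having observable status at
t, which over-represents deaths when much of the cohort is censored
before t; at such horizons the test rejects even well-calibrated models.
It is reliable at horizons within typical follow-up, and the
misspecification experiments below therefore use uncensored cohorts.  A
Kaplan–Meier-within-decile variant would remove the bias and is noted as
an alternative.

**D-calibration.**  For each death at dᵢ, S_i(dᵢ) adds one count to its
decile bin ([0.9, 1.0] right-closed; boundary values go to the bin
above).  Each censored patient spreads one unit of mass uniformly over
[0, S_i(cᵢ)], the conditional distribution of S_i(T) given T > cᵢ under a
calibrated curve.  Expected counts are total/10; χ² with dof = 9 (no
parameters are estimated from the binned values).  Mass is conserved
exactly: Σ observed = #deaths + #censored.  The companion summary
`fraction_dead_before_median` counts deaths strictly before the patient's
predicted median; it equals ½ only in uncensored cohorts — under heavy
censoring observed deaths are biased early, and the reported value will
exceed ½ without indicating miscalibration.

**Cross-validation.**  Variable selection and model fitting run inside
each training fold; out-of-fold curves are pooled and all metrics are
computed once on the pooled set (per-fold D-calibration p-values are also
reported).  Fold assignment is deterministic given the seed; `group_by =
"center"` partitions centers, not patients, so no center contributes to
both training and test of any fold.

## The synthetic generator

Weibull proportional hazards, S(t|x) = exp(−(t/scale)^shape ·
exp(βᵀ(x−ref))), gives closed-form curves, survival probabilities and
quantiles for every patient — the analytic oracle behind the calibration
identities.  The registry blueprint reproduces the covariate list and
marginal moments of a published liver-transplant cohort (age 47.4 ± 13.5,
albumin 2.97 ± 0.74, MELD 20.7 ± 8.6, ~11% diabetes, ~78% transplanted
from home, four blood groups, 121 centers with Dirichlet-multinomial
sizes) with modest effects on age, albumin, diabetes and pre-transplant
location (cohort hazard-ratio estimates are *not* used as generative
truth), administrative censoring at 4300 days plus exponential loss to
follow-up (mean 2500 days), yielding registry-like event fractions
(~15–20%).  It does **not** emulate coding quirks, correlated laboratory
panels, diagnosis-specific exclusion cascades, or informative censoring —
so passing tests demonstrate correctness of the machinery under clean
assumptions, not robustness to those real-data features.

The misspecification scenario is piecewise-exponential with one
Bernoulli(½) covariate whose log hazard effect is +1.0 before day 730 and
−1.5 after.  With a binary covariate each PSSP interval classifier is
saturated (exactly specified), while no proportional-hazards model can
represent the reversal; this is the cleanest construction in which "Cox
is wrong and the interval model is right".  In the contrast experiment
(train n = 4000, test n = 1500, uncensored, PSSP grid of 10 event-time
quantiles augmented with the four evaluation horizons) Cox-KP fails the
10-year Hosmer–Lemeshow test in essentially every replicate while PSSP
fails at roughly the nominal rate.

## Problem sizes

The calibration identities use n = 2000 uncensored patients (100
replicates for the decile-uniformity check); parameter recovery uses
n = 2000 (Cox) and n = 5000 (interval coefficients); the calibration
contrast uses 20 replicates.  These sizes give Monte-Carlo error well
inside the asserted tolerances (e.g. the ±3-percentage-point band on the
median identity is ≈ 2.7 binomial SDs at n = 2000).

## Known limitations

* The interval-classifier construction here is one concrete reading of
  the PSSP family: independent per-interval conditional classifiers
  combined by a telescoping product.  Joint multi-task objectives that
  smooth coefficients across intervals are out of scope.
* The logistic link is an approximation to the complementary-log-log form
  implied by continuous-time hazards; the discrepancy vanishes as
  intervals shrink but can register in large-sample calibration tests
  with coarse grids and strong continuous effects.
* No time-varying covariates, competing risks, stratified baselines or
  penalized Cox.
* Tie handling for the partial likelihood is Efron only.
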