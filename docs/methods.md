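# Methods

## Model

`thermolag` estimates the association between weekly ambient-temperature
exposure and a count-valued developmental score (a 0–100 vocabulary-production
checklist administered around age two) with distributed-lag non-linear models
(DLNMs). For child *i* with score *Y<sub>i</sub>*,

```
Y_i ~ quasi-Poisson(λ_i),
log λ_i = α + β₁ᵀ cb(Temp_pre,i) + β₂ᵀ cb(Temp_post,i) [+ β₃ᵀ cb(AP_pre,i) + β₄ᵀ cb(AP_post,i)] + Σ_k γ_kᵀ X_k,i
```

where `cb(·)` is a cross-basis summarising a subject's weekly exposure history
— 30 gestational weeks counted from conception for the prenatal period, 91
weeks from birth for the postnatal period — and `X_k` are covariates (sex,
parental education, parity, deprivation, greenness, age at testing). The
optional pollutant cross-bases (`AP`) estimate the temperature effect over and
above air pollution.

### Cross-basis

The cross-basis is the tensor product of an exposure-response basis `B` and a
lag-response basis `C` evaluated on the integer lag grid:

```
cb(x_i)[(j,k)] = Σ_l B_j(x_{i,l}) · C_k(l) .
```

Both bases are natural cubic splines without intercept columns (the model
intercept absorbs the constant; omitting it keeps the tensor product full
rank). Defaults are 2 df for the exposure-response curve and 3 df for the
lag-response curve; pollutant blocks use a linear exposure-response (1 df)
with the same lag df. The natural spline is built from the cubic B-spline
design matrix with the two second-derivative-at-boundary constraints removed
by QR projection, and is continued linearly beyond its boundary knots. Knots
sit at equally spaced quantiles (linear-interpolation rule) of the pooled
person-week exposures, boundary knots at the observed extremes; the lag basis
uses the quantiles of the integer lags with boundaries at 1 and n_weeks. The
knots are frozen inside the `CrossBasisSpec` at fit time so prediction uses
the identical basis. Which quantile rule and which reference coding a study
used is rarely reported; making df the only tuning input mirrors how such
analyses are reported in practice.

### Fitting

Coefficients are the Poisson maximum-likelihood IRLS solution (statsmodels
GLM, log link); the quasi-Poisson family enters only through the Pearson
dispersion φ = X²/(n−p), which rescales the covariance: vcov = φ·(XᵀWX)⁻¹.
Since quasi-Poisson has no true likelihood, spline df are compared by
QAIC = −2·ℓ_Poisson/φ̂ + 2p with φ̂ taken from the richest candidate model —
the standard quasi-likelihood analogue of AIC. `select_df` returns the full
criterion table, not just the minimiser, so parsimony and visual inspection of
lag-response curves can also weigh in.

Categorical covariates are dummy-coded against their most frequent level; the
coding is recorded in the coefficient names.

### Effects, windows, strata

Percentile contrasts are computed over the pooled person-week values of each
history: moderate (10th/90th), severe (5th/95th) and extreme (1st/99th)
percentiles, always against the pooled median. Pooling over person-weeks
(rather than subject means or calendar days) uses exactly the values the model
was fitted on; this is a choice the package makes explicit because reference
distributions are often left unstated.

For a contrast x vs reference r, the lag-l log relative risk is
`(B(x)−B(r)) ⊗ C(l) · β` with delta-method SE from the block covariance;
cumulative risks over a lag range sum the prediction rows *before* the
quadratic form, so the full covariance (not a sum of variances) is used and
log cumulative RRs are exactly additive over disjoint lag sets. All intervals
are 95% Wald intervals with multiplier 1.96, with no multiple-testing
correction — single-week significance is deliberately interpreted only
through windows.

A critical window is a maximal run of **at least two** consecutive lags whose
CI excludes 1, all with a common direction; a sign flip splits a run. One
significant week in isolation is not a window: reported critical windows in
this literature span several weeks, and a one-week run is indistinguishable
from a multiplicity artefact. Each window is annotated with the cumulative RR
over its span; RRs convert to percent changes as (1−RR)·100 (reduction) or
(RR−1)·100 (increase).

Sex-stratified analyses fit fully separate models per stratum (their own
covariate coefficients and dispersion) but share the pooled-cohort basis knots
and contrast values, so both strata are compared on the same physical
contrast. Between-group differences use the ratio of risk ratios
RRR = RR₁/RR₂ with CI `exp(log RRR ± 1.96·√(SE₁² + SE₂²))`; the strata are
independent samples, so log-scale variances add. Runs of ≥2 consecutive
significantly different lags are reported as differential windows, and every
within-stratum window also gets both strata's cumulative RRs and their RRR
test.

### Missing covariates

Subjects missing more than 30% of covariate fields are excluded; the rule is
strict (“more than”), so exactly 30% is retained. Remaining holes are filled
by single predictive-mean-matching imputation: one chained pass over the
variables in order of increasing missingness, a least-squares model on
complete cases (predictors: the other covariates, the outcome, and per-period
mean exposures), 5 nearest donors by predicted mean, one drawn uniformly with
a seeded generator. Categorical variables run through the same mechanism on
an integer coding and return a legal level — a defining PMM property the
tests assert. Single imputation (not multiple) is used, so no pooling rules
apply.

## Synthetic cohort generator

The generator emulates the structure of a French national birth cohort so
that every pipeline stage is testable without access data:

* **Enrollment**: births uniform within four 2011 waves (early April, late
  June/early July, late September/early October, late November/early
  December); conception = birth − 266 days.
* **Temperature**: national daily series = annual sinusoid (mean 12 °C,
  amplitude 8 °C, mid-July peak) + AR(1) weather noise (ρ = 0.8, innovation
  SD 2.5 °C); tmax/tmin add/subtract a seasonal diurnal half-range floored at
  0.5 °C, and the single-site simulator clamps to observed metropolitan
  envelopes. Each subject adds a constant site offset (SD 2 °C) and a local
  AR(1) deviation (ρ = 0.8, SD 2 °C). This spatial term is load-bearing:
  with gestation fixed, prenatal and postnatal seasonal profiles are
  deterministic functions of the birth date, and only residential spread lets
  the model separate the two periods — as it does in a real national cohort.
* **Outcome**: NB1 counts, i.e. Var = φ·mean with constant dispersion — the
  exact quasi-Poisson variance function, so model-based SEs are consistent
  and the Pearson dispersion of a correct fit estimates φ (default target
  1.5). Scores are clipped to [0, 100]; the ceiling removes roughly 15% of
  the excess dispersion (fitted φ ≈ 1.27 at the defaults), accepted rather
  than compensated because inflating the generated dispersion concentrates
  variance-function distortion at high means and mis-calibrates Wald tests.
  Covariate effects (log-scale spread ≈ 0.1, dominated by a −0.25 low-
  education deficit) widen the marginal distribution to median ≈ 79–81 with
  IQR ≈ 65–91, a left-skewed shape like real vocabulary scores, though not as
  heavy-tailed as the reference IQR of 59–93 — heavier observed heterogeneity
  would have to come from covariates the model also adjusts for, and pushing
  further degrades the quasi-Poisson variance approximation near the ceiling.
* **Truth surfaces**: `SimulationTruth` carries per-period surfaces f(x, l)
  with f(ref, l) = 0. The recovery scenario projects a Gaussian lag profile
  (peak 0.003 per °C at lag 14.5, width 6) onto the span of the 3-df postnatal
  lag basis, so the generating surface is exactly representable by the default
  model and recovery tests measure estimation error rather than smoothing
  bias; `true_support` is where the projected slope exceeds half its peak
  (weeks 11–43). The peak slope was set by a power argument — roughly four
  per-lag standard errors at n = 3000 for a severe-heat contrast, cumulative
  RR ≈ 0.75 over the support, the order of magnitude of reported multi-week
  postnatal windows.
* **Missingness**: MCAR masking at per-column rates; outcome and anchor dates
  are never masked.

What the generator does **not** emulate: spatially explicit exposure fields,
realistic joint covariate distributions, variable gestation length, outcome
ceilings reached through instrument-specific item behaviour, and non-MCAR
missingness. Passing tests therefore demonstrate the estimator's statistical
properties under a faithful generative twin of the model, not robustness to
every real-data pathology.

## Validation studies and problem sizes

Two seeded replicate studies (module `thermolag.validation`, also run by
`scripts/acceptance.py`) use 20 replicates of n = 3000 cohorts — large enough
that per-lag SEs at a severe contrast are ≈ 0.01 on the log scale, small
enough to rerun routinely:

* **Recovery**: fraction of replicates where a detected deleterious postnatal
  severe-heat window overlaps the true support, and coverage of the true
  cumulative log-RR over the support by the 95% CI.
* **Null calibration**: with f ≡ 0, the per-lag 95%-Wald rejection rate and
  the sex-strata RRR rejection rates, per lag and over a fixed grid of
  non-overlapping 4-week windows. The fixed grid is deliberate: testing RRRs
  only on data-detected windows would condition on selection and no longer
  measure the size of the RRR test itself. Note that lag tests within one
  replicate are strongly correlated (the whole fitted surface moves
  together), so these rates carry replicate-level Monte-Carlo noise of one
  to two percentage points.

## Numerical choices and degenerate inputs

* IRLS convergence: relative deviance change < 1e-9, max 50 iterations;
  non-convergence raises with the deviance trace.
* Rank deficiency is detected before fitting (pivoted QR) and the collinear
  columns are named; requesting PM2.5 and PM10 together is refused up front
  because their daily correlation exceeds 0.9.
* Constant exposure vectors, df exceeding the number of distinct values, and
  quantile knots colliding with boundaries all raise informative errors.
* Prediction at exposures outside the var-basis boundary warns (linear
  extrapolation of the natural spline) rather than failing.
* Weekly histories demand complete daily coverage; partial trailing weeks are
  an error, not silently averaged.
* Replicate seeds derive as `seed·1000 + replicate` (kept below 2³¹).

## Known limitations

* Model-based (not sandwich) covariance, per the quasi-Poisson convention the
  pipeline reproduces; under variance-function misspecification (e.g. strong
  ceiling effects) Wald tests can drift from nominal size.
* The minimum window length (2) and the pooled person-week reference
  distribution are conventions; both are parameters of the public API.
* Single imputation understates imputation uncertainty by construction.
* The lag-response bases are unpenalised; df selection is the only smoothing
  control.
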