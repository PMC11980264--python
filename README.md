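# thermolag

Distributed-lag non-linear models (DLNMs) for the effect of weekly prenatal
and postnatal ambient-temperature exposure on a count-valued developmental
score, for environmental-epidemiology analyses of birth cohorts.

Early-life temperature stress is a candidate risk factor for
neurodevelopment: both the timing and the intensity of exposure matter, so
the estimand is a full exposure-lag-response surface rather than a single
coefficient. `thermolag` implements the complete pipeline:

* daily environmental series → fixed-length weekly exposure histories
  (30 gestational weeks from conception; 91 weeks from birth);
* natural-cubic-spline **cross-bases** `cb(x)[(j,k)] = Σ_l B_j(x_l)·C_k(l)`
  coupling the exposure-response curve `B` (2 df) with the lag-response
  curve `C` (3 df);
* quasi-Poisson GLM
  `log λ_i = α + β₁ᵀcb(Temp_pre) + β₂ᵀcb(Temp_post) + Σ_k γ_kᵀX_k`
  (dispersion-scaled covariance, QAIC for df selection), optionally extended
  with linear-response pollutant cross-bases (PM2.5, PM10, NO₂) to estimate
  the direct temperature effect;
* relative risks for percentile contrasts vs the median — moderate
  (10th/90th), severe (5th/95th), extreme (1st/99th) — per lag week and
  cumulatively, with full-covariance delta-method CIs;
* **critical windows**: maximal runs of ≥2 consecutive significant weeks in a
  common direction, with the cumulative RR over the window and its percent
  change (1−RR)·100 / (RR−1)·100;
* sex-stratified fits compared by ratios of risk ratios,
  `RRR = RR₁/RR₂`, CI `exp(log RRR ± 1.96·√(SE₁²+SE₂²))`;
* covariate missingness handling (>30% exclusion rule, predictive-mean-
  matching single imputation);
* a synthetic-cohort generator with known ground-truth surfaces, so every
  stage is testable end to end without any restricted cohort data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

`examples/02_fit_and_windows.py` simulates 3,000 children whose expected
score is lowered by sustained early-postnatal heat, then runs the full
pipeline:

```text
true deleterious postnatal support: weeks 11-43
n=3000, p=23, Pearson dispersion=1.203

   period  start_week  end_week   direction       rr   ci_low  ci_high  percent_change
postnatal           2        49 deleterious 0.743339 0.662902 0.833536      -25.666090
postnatal          90        91 deleterious 0.990193 0.980760 0.999717       -0.980676
```

Reading the first row: sustained exposure at the 95th-percentile temperature
(vs the pooled median) throughout postnatal weeks 2–49 multiplies the
expected score by 0.74 (95% CI 0.66–0.83), i.e. a 25.7% reduction — and the
detected window brackets the true support of the generating surface
(weeks 11–43). Other entry points are `examples/01`–`05` (simulation,
pollutant adjustment, sex strata, imputation) and the thin CLI
(`thermolag simulate|impute|fit|effects|windows|compare-sex|run-all`).

As a quick orientation to the effect scale this machinery targets: a
cumulative RR of 0.968 over a six-week gestational window corresponds to a
3.2% score reduction, and an RR of 1.033 to a 3.3% increase
(`thermolag.rr_to_percent`).

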