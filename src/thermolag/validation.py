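"""Replicate-based validation studies on the synthetic generator.

Two seeded studies quantify how the full pipeline behaves under known
truth:

* :func:`recovery_study` — cohorts drawn from a deleterious postnatal heat
  surface; measures how often a detected deleterious postnatal window
  overlaps the true support and how often the 95% CI of the cumulative
  log-RR over the true support covers the generating value.
* :func:`null_calibration_study` — cohorts with no temperature effect;
  measures the per-lag false-positive rate of the 95% Wald test and the
  false-positive rate of ratio-of-risk-ratio tests between the two sex
  strata, per lag and over a fixed grid of 4-week windows (a fixed grid
  avoids conditioning the type-I-error estimate on data-driven window
  selection).

Replicate seeds are derived as ``seed * 1000 + replicate`` so studies are
reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np

from .effects import cumulative_effect
from .exposure import percentile_contrasts
from .pipeline import RunConfig, run_main
from .strata import ratio_of_rr
from .synthetic import (
    inject_missingness,
    null_truth,
    postnatal_heat_hump_truth,
    simulate_cohort,
    true_cumulative_log_rr,
)

__all__ = ["recovery_study", "null_calibration_study"]


def _rep_seed(seed: int, rep: int) -> int:
    return (seed * 1000 + rep) % (2**31 - 1)


def recovery_study(n: int = 3000, n_reps: int = 20, seed: int = 0) -> dict:
    """Window detection and CI coverage under the postnatal heat surface."""
    truth = postnatal_heat_hump_truth()
    lo, hi = truth.true_support
    support = np.arange(lo, hi + 1)
    detected = 0
    covered = 0
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        cohort, daily = simulate_cohort(n, truth, seed=s)
        cohort = inject_missingness(
            cohort, {"edu": 0.10, "deprivation": 0.05}, seed=s
        )
        res = run_main(RunConfig(seed=s), cohort=cohort, daily=daily)
        wins = res["windows"].query(
            "period == 'postnatal' and severity == 'heat:severe' "
            "and direction == 'deleterious'"
        )
        if ((wins["start_week"] <= hi) & (wins["end_week"] >= lo)).any():
            detected += 1
        ctr = percentile_contrasts(res["histories"]["temp_post"])
        exposure, ref = ctr["heat"]["severe"][1], ctr["reference"]
        est = cumulative_effect(
            res["fit"], res["specs"]["temp_post"], "temp_post", exposure, ref, support
        )
        truth_lr = true_cumulative_log_rr(truth, exposure, ref, support)
        if np.log(est.ci_low) <= truth_lr <= np.log(est.ci_high):
            covered += 1
    return {
        "n": n,
        "n_reps": n_reps,
        "detection_rate": detected / n_reps,
        "coverage_rate": covered / n_reps,
        "true_support": (lo, hi),
    }


def _fixed_spans(n_weeks: int, width: int = 4) -> list[range]:
    return [
        range(start, start + width)
        for start in range(1, n_weeks - width + 2, width)
    ]


def null_calibration_study(n: int = 3000, n_reps: int = 20, seed: int = 0) -> dict:
    """False-positive rates of lag tests and sex-strata RRR tests at the null."""
    lag_tests = lag_hits = 0
    rrr_lag_tests = rrr_lag_hits = 0
    rrr_win_tests = rrr_win_hits = 0
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        cohort, daily = simulate_cohort(n, null_truth(), seed=s)
        res = run_main(
            RunConfig(seed=s, impute=False, stratify_by_sex=True),
            cohort=cohort,
            daily=daily,
        )
        eff = res["effects"].query("severity == 'heat:severe'")
        lag_tests += len(eff)
        lag_hits += int(eff["significant"].sum())
        strat = res["stratified"]
        for name in ("temp_pre", "temp_post"):
            series = strat["rrr_per_lag"][name]
            rrr_lag_tests += len(series)
            rrr_lag_hits += sum(r.significant for r in series)
            n_weeks = res["histories"][name].n_weeks
            g1, g2 = strat["strata"]
            cum1 = strat["per_stratum"][g1]["blocks"][name]["cumulative_fn"]
            cum2 = strat["per_stratum"][g2]["blocks"][name]["cumulative_fn"]
            for span in _fixed_spans(n_weeks):
                c1, c2 = cum1(span), cum2(span)
                r = ratio_of_rr(c1.rr, c1.se_log_rr, c2.rr, c2.se_log_rr,
                                scope="per-window")
                rrr_win_tests += 1
                rrr_win_hits += int(r.significant)
    return {
        "n": n,
        "n_reps": n_reps,
        "per_lag_significance_rate": lag_hits / lag_tests,
        "rrr_per_lag_significance_rate": rrr_lag_hits / rrr_lag_tests,
        "rrr_window_significance_rate": rrr_win_hits / rrr_win_tests,
        "n_lag_tests": lag_tests,
        "n_rrr_window_tests": rrr_win_tests,
    }
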