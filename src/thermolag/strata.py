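"""Sex-stratified fits and between-group inference via ratios of risk ratios.

Each stratum gets its own fully separate model fit (its own covariate
coefficients), using the SAME frozen cross-basis spec and the same
percentile contrast values as the pooled cohort so both strata are compared
on an identical physical exposure contrast.  Between-group differences use
the ratio of risk ratios

    RRR = RR1 / RR2,
    95% CI = exp( log RRR ± 1.96 * sqrt(SE1² + SE2²) )

with SE1, SE2 the delta-method standard errors of the two log RRs; the two
strata are independent samples, so the log-scale variances add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import (
    EffectEstimate,
    Z95,
    cumulative_effect,
    find_windows,
    lag_effects,
)
from .model import fit_dlnm

__all__ = ["RRRResult", "ratio_of_rr", "stratified_analysis"]


@dataclass(frozen=True)
class RRRResult:
    rr_group1: float
    rr_group2: float
    se1: float  # SE of log RR1
    se2: float
    scope: str = "per-lag"  # or "per-window"
    lag: int | None = None

    @property
    def rrr(self) -> float:
        return self.rr_group1 / self.rr_group2

    @property
    def ci_low(self) -> float:
        return float(np.exp(np.log(self.rrr) - Z95 * np.hypot(self.se1, self.se2)))

    @property
    def ci_high(self) -> float:
        return float(np.exp(np.log(self.rrr) + Z95 * np.hypot(self.se1, self.se2)))

    @property
    def significant(self) -> bool:
        return bool(self.ci_low > 1.0 or self.ci_high < 1.0)


def ratio_of_rr(
    rr1: float, se1: float, rr2: float, se2: float, scope: str = "per-lag",
    lag: int | None = None,
) -> RRRResult:
    """Ratio of two risk ratios with its 95% CI."""
    if rr1 <= 0 or rr2 <= 0:
        raise ValueError("relative risks must be positive")
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    return RRRResult(rr1, rr2, se1, se2, scope=scope, lag=lag)


def _rrr_from_effects(e1: EffectEstimate, e2: EffectEstimate, scope: str) -> RRRResult:
    return ratio_of_rr(e1.rr, e1.se_log_rr, e2.rr, e2.se_log_rr, scope=scope, lag=e1.lag)


def stratified_analysis(
    cohort: pd.DataFrame,
    histories: dict,
    specs: dict,
    contrasts: dict,
    covariates: list[str] | None = None,
    outcome: str = "y",
    strata_col: str = "sex",
    min_window: int = 2,
) -> dict:
    """Fit the model per stratum and compare strata lag by lag.

    ``histories`` maps block name -> full-cohort ExposureHistory; ``specs``
    the matching frozen CrossBasisSpec per block; ``contrasts`` maps block
    name -> dict with keys ``exposure`` and ``reference`` (the full-cohort
    percentile contrast to evaluate).

    Returns a dict with, per stratum, the fit and its per-block lag effects
    and critical windows; per-lag RRR series; RRR critical windows
    (>= ``min_window`` consecutive significantly different lags); and for
    every within-stratum window, both strata's cumulative RRs with their RRR
    test.
    """
    levels = [lv for lv in pd.unique(cohort[strata_col]) if pd.notna(lv)]
    if len(levels) != 2:
        raise ValueError(
            f"stratified analysis needs exactly two strata, found {levels!r}"
        )
    levels = sorted(levels, key=str)

    per_stratum: dict = {}
    for lv in levels:
        mask = (cohort[strata_col] == lv).to_numpy()
        sub = cohort.loc[mask]
        if mask.sum() < 2:
            raise ValueError(f"stratum {lv!r} too small to fit")
        sub_hist = {name: h.subset(mask) for name, h in histories.items()}
        covs = [c for c in (covariates or []) if c != strata_col]
        try:
            fit = fit_dlnm(sub, sub_hist, specs, covs, outcome)
        except ValueError as err:
            raise ValueError(f"stratum {lv!r}: {err}") from err
        block_results = {}
        for name, spec in specs.items():
            ctr = contrasts[name]
            ests = lag_effects(
                fit, spec, name, ctr["exposure"], ctr["reference"],
                period=histories[name].period, modality=histories[name].modality,
            )
            cum_fn = lambda lags, _s=spec, _n=name, _c=ctr, _f=fit: cumulative_effect(
                _f, _s, _n, _c["exposure"], _c["reference"], lags
            )
            block_results[name] = {
                "effects": ests,
                "windows": find_windows(ests, min_length=min_window, cumulative_fn=cum_fn),
                "cumulative_fn": cum_fn,
            }
        per_stratum[lv] = {"fit": fit, "blocks": block_results, "n": int(mask.sum())}

    g1, g2 = levels
    rrr_per_lag: dict = {}
    rrr_windows: dict = {}
    window_tests: list[dict] = []
    for name in specs:
        e1 = per_stratum[g1]["blocks"][name]["effects"]
        e2 = per_stratum[g2]["blocks"][name]["effects"]
        series = [_rrr_from_effects(a, b, "per-lag") for a, b in zip(e1, e2)]
        rrr_per_lag[name] = series
        # significant-RRR runs, reusing the window machinery on pseudo-effects
        pseudo = [
            EffectEstimate(np.log(r.rrr), np.hypot(r.se1, r.se2), lag=r.lag)
            for r in series
        ]
        rrr_windows[name] = find_windows(pseudo, min_length=min_window)
        # within-stratum windows: cumulative RRs of both strata + RRR test
        for lv in levels:
            for w in per_stratum[lv]["blocks"][name]["windows"]:
                c1 = per_stratum[g1]["blocks"][name]["cumulative_fn"](w.lags)
                c2 = per_stratum[g2]["blocks"][name]["cumulative_fn"](w.lags)
                window_tests.append(
                    {
                        "block": name,
                        "found_in": lv,
                        "start_week": w.start_week,
                        "end_week": w.end_week,
                        "rrr": _rrr_from_effects(c1, c2, "per-window"),
                        "cum_rr_1": c1,
                        "cum_rr_2": c2,
                    }
                )
    return {
        "strata": levels,
        "per_stratum": per_stratum,
        "rrr_per_lag": rrr_per_lag,
        "rrr_windows": rrr_windows,
        "window_tests": window_tests,
    }


def rrr_frame(series: list[RRRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lag": [r.lag for r in series],
            "rr_group1": [r.rr_group1 for r in series],
            "rr_group2": [r.rr_group2 for r in series],
            "rrr": [r.rrr for r in series],
            "ci_low": [r.ci_low for r in series],
            "ci_high": [r.ci_high for r in series],
            "significant": [r.significant for r in series],
        }
    )
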