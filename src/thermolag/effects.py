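"""Relative risks, critical windows and percent-change conversion.

Given a fitted model and the frozen cross-basis spec of one block, the
lag-specific log relative risk of a one-week exposure at value x versus the
median reference is ``r_l' beta`` with r_l the prediction row for lag l; its
standard error comes from the delta method, ``sqrt(r_l' Sigma r_l)`` with
Sigma the dispersion-scaled covariance of the block.  Cumulative risks over
a lag range sum the rows first (full covariance, not a sum of variances),
so log cumulative RRs are exactly additive over disjoint lag sets.

A critical window is a maximal run of at least two consecutive lags whose
95% Wald CI excludes 1, all in the same direction; each window is annotated
with the cumulative RR over its span.  RRs convert to percent changes as
(1-RR)*100 (reduction, RR < 1) or (RR-1)*100 (increase, RR > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbasis import CrossBasisSpec, prediction_rows
from .model import FittedDlnm

__all__ = [
    "EffectEstimate",
    "CriticalWindow",
    "PercentChange",
    "lag_effects",
    "cumulative_effect",
    "find_windows",
    "rr_to_percent",
    "effects_frame",
    "windows_frame",
]

Z95 = 1.96  # Wald multiplier for 95% confidence intervals


@dataclass(frozen=True)
class EffectEstimate:
    log_rr: float
    se_log_rr: float
    lag: int | None = None  # None for cumulative estimates
    period: str | None = None
    modality: str | None = None
    severity: str | None = None

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_rr - Z95 * self.se_log_rr))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_rr + Z95 * self.se_log_rr))

    @property
    def significant(self) -> bool:
        """True iff the 95% CI excludes RR = 1."""
        return bool(self.ci_low > 1.0 or self.ci_high < 1.0)


@dataclass(frozen=True)
class CriticalWindow:
    start_week: int
    end_week: int  # inclusive, 1-based
    cumulative: EffectEstimate | None
    direction: str  # "deleterious" (RR < 1 for this outcome) or "protective"
    period: str | None = None
    modality: str | None = None
    severity: str | None = None

    def __post_init__(self):
        if self.start_week > self.end_week:
            raise ValueError("window start must not exceed end")

    @property
    def lags(self) -> range:
        return range(self.start_week, self.end_week + 1)


def _contrast_effects(
    fit: FittedDlnm,
    spec: CrossBasisSpec,
    block: str,
    rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    if block not in fit.blocks:
        raise KeyError(f"block {block!r} not present in fit (has {list(fit.blocks)})")
    beta = fit.block_params(block)
    sigma = fit.block_vcov(block)
    if beta.size != spec.n_columns:
        raise ValueError(
            f"block {block!r} has {beta.size} coefficients but the spec "
            f"implies {spec.n_columns}"
        )
    log_rr = rows @ beta
    var = np.einsum("lj,jk,lk->l", rows, sigma, rows)
    return log_rr, np.sqrt(np.maximum(var, 0.0))


def lag_effects(
    fit: FittedDlnm,
    spec: CrossBasisSpec,
    block: str,
    exposure: float,
    reference: float,
    lags=None,
    **labels,
) -> list[EffectEstimate]:
    """Per-lag RR of a one-week exposure at ``exposure`` vs ``reference``."""
    if lags is None:
        lags = np.arange(1, spec.n_weeks + 1)
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    rows = prediction_rows(spec, exposure, reference, lags)
    log_rr, se = _contrast_effects(fit, spec, block, rows)
    return [
        EffectEstimate(float(lr), float(s), lag=int(l), **labels)
        for lr, s, l in zip(log_rr, se, lags)
    ]


def cumulative_effect(
    fit: FittedDlnm,
    spec: CrossBasisSpec,
    block: str,
    exposure: float,
    reference: float,
    lags,
    **labels,
) -> EffectEstimate:
    """Cumulative RR of sustained exposure throughout the given lag range.

    The log cumulative RR is the sum of the per-lag log RRs; its variance
    uses the summed prediction row against the full block covariance.
    """
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    rows = prediction_rows(spec, exposure, reference, lags)
    total = rows.sum(axis=0, keepdims=True)
    log_rr, se = _contrast_effects(fit, spec, block, total)
    return EffectEstimate(float(log_rr[0]), float(se[0]), lag=None, **labels)


def find_windows(
    estimates: list[EffectEstimate],
    min_length: int = 2,
    cumulative_fn=None,
) -> list[CriticalWindow]:
    """Maximal runs of consecutive significant lags with a common direction.

    ``estimates`` must cover every lag of the period in order.  Runs shorter
    than ``min_length`` weeks are dropped; a sign flip inside a run splits
    it.  If ``cumulative_fn`` is given it is called with the inclusive lag
    range of each window and must return the window's cumulative
    EffectEstimate.
    """
    if not estimates:
        return []
    ests = sorted(estimates, key=lambda e: e.lag)
    lags = [e.lag for e in ests]
    if lags != list(range(lags[0], lags[0] + len(lags))):
        raise ValueError("estimates must cover consecutive lags without gaps")

    windows: list[CriticalWindow] = []
    run: list[EffectEstimate] = []

    def flush():
        if len(run) >= min_length:
            first = run[0]
            direction = "deleterious" if first.log_rr < 0 else "protective"
            start, end = run[0].lag, run[-1].lag
            cum = cumulative_fn(range(start, end + 1)) if cumulative_fn else None
            windows.append(
                CriticalWindow(
                    start, end, cum, direction,
                    period=first.period, modality=first.modality,
                    severity=first.severity,
                )
            )
        run.clear()

    for e in ests:
        if not e.significant:
            flush()
            continue
        if run and np.sign(e.log_rr) != np.sign(run[-1].log_rr):
            flush()
        run.append(e)
    flush()
    return windows


@dataclass(frozen=True)
class PercentChange:
    value: float  # magnitude on the percent scale
    direction: str  # "reduction" | "increase" | "none"

    def __str__(self) -> str:
        if self.direction == "none":
            return "0% change"
        return f"{self.value:.1f}% {self.direction}"


def rr_to_percent(rr: float) -> PercentChange:
    """Express an RR as the percent change in the expected score.

    RR < 1 is a reduction of (1-RR)*100 percent; RR > 1 an increase of
    (RR-1)*100 percent.
    """
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if rr < 1.0:
        return PercentChange((1.0 - rr) * 100.0, "reduction")
    if rr > 1.0:
        return PercentChange((rr - 1.0) * 100.0, "increase")
    return PercentChange(0.0, "none")


def effects_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy per-lag effects table (one row per lag)."""
    return pd.DataFrame(
        {
            "period": [e.period for e in estimates],
            "modality": [e.modality for e in estimates],
            "severity": [e.severity for e in estimates],
            "lag": [e.lag for e in estimates],
            "rr": [e.rr for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "significant": [e.significant for e in estimates],
        }
    )


def windows_frame(windows: list[CriticalWindow]) -> pd.DataFrame:
    """Tidy windows table with cumulative RR and percent change."""
    rows = []
    for w in windows:
        c = w.cumulative
        pct = rr_to_percent(c.rr) if c is not None else None
        rows.append(
            {
                "period": w.period,
                "modality": w.modality,
                "severity": w.severity,
                "start_week": w.start_week,
                "end_week": w.end_week,
                "direction": w.direction,
                "rr": c.rr if c else np.nan,
                "ci_low": c.ci_low if c else np.nan,
                "ci_high": c.ci_high if c else np.nan,
                "percent_change": (
                    0.0 if pct is None or pct.direction == "none"
                    else (-pct.value if pct.direction == "reduction" else pct.value)
                ),
            }
        )
    cols = [
        "period", "modality", "severity", "start_week", "end_week",
        "direction", "rr", "ci_low", "ci_high", "percent_change",
    ]
    return pd.DataFrame(rows, columns=cols)


def plot_lag_response(estimates: list[EffectEstimate], ax=None, title: str | None = None):
    """Lag-response plot: solid RR line, dashed 95% CI, shaded significant spans."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    lags = [e.lag for e in estimates]
    rr = [e.rr for e in estimates]
    lo = [e.ci_low for e in estimates]
    hi = [e.ci_high for e in estimates]
    sig = np.array([e.significant for e in estimates])
    ax.plot(lags, rr, "-", color="firebrick")
    ax.plot(lags, lo, "--", color="firebrick", lw=0.8)
    ax.plot(lags, hi, "--", color="firebrick", lw=0.8)
    ax.axhline(1.0, color="grey", lw=0.8)
    for w in find_windows(estimates):
        ax.axvspan(w.start_week - 0.5, w.end_week + 0.5, color="mistyrose", zorder=0)
    ax.set_xlabel("lag (weeks)")
    ax.set_ylabel("RR")
    if title:
        ax.set_title(title)
    return ax
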