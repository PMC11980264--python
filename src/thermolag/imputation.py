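"""Covariate missingness handling: exclusion rule + predictive mean matching.

Subjects missing more than 30% of their covariate fields are excluded
outright.  Remaining missing cells are filled by single imputation with
predictive mean matching (PMM): a linear model fitted on complete cases
predicts the incomplete case's value, the five observed cases with the
closest predictions act as donors, and one donor's OBSERVED value is drawn
uniformly — so imputed values are always values that actually occur in the
data.  Categorical variables go through the same mechanism on an internal
integer coding and come back as a legal level.  One chained pass is made
over the variables in order of increasing missingness; predictors should
include the per-period mean exposures, the other covariates and the
outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MissingnessReport", "drop_high_missing", "pmm_impute"]

MAX_MISSING_FRACTION = 0.30  # strictly-greater-than rule


@dataclass
class MissingnessReport:
    covariate_missing: dict[str, float]
    subject_missing: pd.Series
    subjects_dropped: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "covariate_missing": self.covariate_missing,
            "n_dropped": len(self.subjects_dropped),
            "subjects_dropped": [str(s) for s in self.subjects_dropped],
            "warnings": self.warnings,
        }


def drop_high_missing(
    cohort: pd.DataFrame,
    covariates: list[str],
    id_col: str = "subject_id",
) -> tuple[pd.DataFrame, MissingnessReport]:
    """Remove subjects with more than 30% of covariate fields missing.

    Also verifies that after exclusion no retained covariate is itself more
    than 30% missing, warning (not failing) when violated.
    """
    frac = cohort[covariates].isna().mean(axis=1)
    keep = frac <= MAX_MISSING_FRACTION
    dropped = cohort.loc[~keep, id_col].tolist() if id_col in cohort else list(
        cohort.index[~keep]
    )
    out = cohort.loc[keep].reset_index(drop=True)
    cov_missing = {c: float(out[c].isna().mean()) for c in covariates}
    warns = [
        f"covariate {c!r} still {100 * f:.1f}% missing after exclusion"
        for c, f in cov_missing.items()
        if f > MAX_MISSING_FRACTION
    ]
    report = MissingnessReport(cov_missing, frac, dropped, warns)
    return out, report


def _code_predictors(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design for the PMM linear model (dummy-coded categoricals)."""
    cols = [np.ones(len(df))]
    for p in predictors:
        s = df[p]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = pd.unique(s.dropna())
            for lv in sorted(levels, key=str)[1:]:
                cols.append((s == lv).to_numpy(dtype=float))
        else:
            v = s.to_numpy(dtype=float)
            v = np.where(np.isfinite(v), v, np.nanmean(v))
            cols.append(v)
    return np.column_stack(cols)


def pmm_impute(
    cohort: pd.DataFrame,
    variables: list[str],
    predictors: list[str],
    donors: int = 5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fill missing cells of ``variables`` by predictive mean matching.

    A single chained pass visits the variables in order of increasing
    missingness.  For each, a least-squares model of the (coded) variable on
    the coded predictors is fitted on currently-complete cases; the
    ``donors`` observed cases with predictions closest to each incomplete
    case's prediction are candidates and one is drawn uniformly (seeded).
    Predictors with their own missing cells enter the linear model
    mean-filled; their actual values are imputed when their turn comes.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    missing_frac = {v: out[v].isna().mean() for v in variables}
    order = sorted(variables, key=lambda v: (missing_frac[v], v))

    for var in order:
        miss = out[var].isna().to_numpy()
        if not miss.any():
            continue
        obs = ~miss
        if not obs.any():
            raise ValueError(f"variable {var!r} has no observed values to donate")
        preds = [p for p in predictors if p != var]
        x = _code_predictors(out, preds)
        s = out[var]
        categorical = (
            s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool
        )
        if categorical:
            levels = sorted(pd.unique(s.dropna()), key=str)
            code = {lv: i for i, lv in enumerate(levels)}
            y_obs = s[obs].map(code).to_numpy(dtype=float)
        else:
            y_obs = s[obs].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(x[obs], y_obs, rcond=None)
        pred_obs = x[obs] @ beta
        pred_mis = x[miss] @ beta
        k = min(donors, obs.sum())
        # donor pool: k observed cases with closest predicted means
        dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
        pool = np.argpartition(dist, k - 1, axis=1)[:, :k]
        choice = pool[np.arange(pool.shape[0]), rng.integers(0, k, size=pool.shape[0])]
        donated = s[obs].to_numpy()[choice]
        col = out[var].copy()
        col[miss] = donated
        out[var] = col
    return out
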