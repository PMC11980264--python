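"""Cross-basis construction and prediction rows.

The cross-basis encodes a bivariate exposure-lag-response surface as a
tensor product of a var (exposure-response) basis B and a lag-response
basis C evaluated on the integer lag grid 1..n_weeks:

    design[i, (j,k)] = sum_l  B_j(x_{i,l}) * C_k(l)

Fitting a GLM on these columns estimates the surface coefficients; the same
spec then produces *prediction rows* (B(x) - B(x_ref)) ⊗ C(l) whose inner
product with the coefficient block is the lag-l log relative risk of a
one-week exposure at x versus the reference.  The var basis is centred only
at prediction time, so a single fit serves every percentile contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, check_extrapolation, eval_basis, place_knots
from .exposure import ExposureHistory

__all__ = ["CrossBasisSpec", "CrossBasis", "spec_from_history", "build_crossbasis", "prediction_rows"]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Frozen pair of bases defining one cross-basis block.

    ``var_basis`` holds the knots computed from the pooled person-week
    exposures of the history the model was fitted on; freezing them in the
    spec guarantees prediction uses the identical basis.  ``lag_basis`` is
    evaluated on the integer lags 1..n_weeks with boundary knots at 1 and
    n_weeks.
    """

    var_basis: BasisSpec
    lag_basis: BasisSpec
    n_weeks: int

    @property
    def df_var(self) -> int:
        return self.var_basis.df

    @property
    def df_lag(self) -> int:
        return self.lag_basis.df

    @property
    def n_columns(self) -> int:
        return self.df_var * self.df_lag

    def column_index(self) -> list[tuple[int, int]]:
        """(j, k) pairs: column j*df_lag + k pairs var column j with lag column k."""
        return [(j, k) for j in range(self.df_var) for k in range(self.df_lag)]

    def lag_matrix(self) -> np.ndarray:
        lags = np.arange(1, self.n_weeks + 1, dtype=float)
        return eval_basis(self.lag_basis, lags)


def spec_from_history(
    history: ExposureHistory, df_var: int = 2, df_lag: int = 3
) -> CrossBasisSpec:
    """Build a CrossBasisSpec with knots from the pooled person-week values.

    Defaults follow the temperature analysis: 2 df for the exposure-response
    curve, 3 df for the lag-response curve.  Pollutant blocks use
    ``df_var=1`` (linear exposure-response) with the same lag df.
    """
    var_basis = place_knots(history.matrix.ravel(), df_var)
    lag_basis = place_knots(np.arange(1, history.n_weeks + 1, dtype=float), df_lag)
    return CrossBasisSpec(var_basis, lag_basis, history.n_weeks)


@dataclass
class CrossBasis:
    """Design-matrix block plus everything needed to predict from it."""

    design: np.ndarray  # n_subjects x (df_var * df_lag)
    spec: CrossBasisSpec
    subjects: np.ndarray

    @property
    def column_index(self) -> list[tuple[int, int]]:
        return self.spec.column_index()


def build_crossbasis(history: ExposureHistory, spec: CrossBasisSpec) -> CrossBasis:
    """Sum the var⊗lag tensor product over each subject's exposure history."""
    if spec.n_weeks != history.n_weeks:
        raise ValueError(
            f"spec expects {spec.n_weeks} weeks but history has {history.n_weeks}"
        )
    n, L = history.matrix.shape
    b = eval_basis(spec.var_basis, history.matrix.ravel()).reshape(n, L, spec.df_var)
    c = spec.lag_matrix()  # L x df_lag
    design = np.einsum("ilj,lk->ijk", b, c).reshape(n, spec.n_columns)
    return CrossBasis(design, spec, history.subjects)


def prediction_rows(
    spec: CrossBasisSpec,
    exposure_value: float,
    reference: float,
    lags=None,
) -> np.ndarray:
    """Contrast rows for a one-week exposure at ``exposure_value`` vs reference.

    Row for lag l is ``(B(exposure) - B(reference)) ⊗ C(l)``; its inner
    product with the block coefficients is the lag-l log-RR.  Values outside
    the var-basis boundary knots trigger an extrapolation warning, not an
    error.
    """
    if lags is None:
        lags = np.arange(1, spec.n_weeks + 1)
    lags = np.atleast_1d(np.asarray(lags, dtype=int))
    if lags.size == 0:
        raise ValueError("empty lag set")
    if lags.min() < 1 or lags.max() > spec.n_weeks:
        raise ValueError(f"lags must lie in 1..{spec.n_weeks}")
    check_extrapolation(
        spec.var_basis, [exposure_value, reference], context="prediction_rows"
    )
    db = (
        eval_basis(spec.var_basis, [exposure_value])
        - eval_basis(spec.var_basis, [reference])
    )[0]  # df_var
    c = eval_basis(spec.lag_basis, lags.astype(float))  # len(lags) x df_lag
    return np.einsum("j,lk->ljk", db, c).reshape(len(lags), spec.n_columns)
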