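"""Quasi-Poisson DLNM fitting and spline-df selection.

The outcome is a bounded word count (0-100) modelled as overdispersed
Poisson with a log link:

    log lambda_i = alpha + beta_pre' cb(pre) + beta_post' cb(post)
                   [+ pollutant cross-bases] + gamma' X_i

Point estimates are the Poisson maximum-likelihood (IRLS) solution; the
quasi-Poisson family only rescales the covariance by the Pearson dispersion
phi = X^2 / (n - p).  Degrees of freedom for the spline bases are chosen by
QAIC = -2 loglik / phi_hat + 2p with phi_hat taken from the richest
candidate model, the standard quasi-likelihood analogue of AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .crossbasis import CrossBasis, build_crossbasis, spec_from_history

__all__ = ["FittedDlnm", "fit_quasipoisson", "assemble_design", "select_df"]


@dataclass
class FittedDlnm:
    """Coefficients and dispersion-scaled covariance of one fitted model."""

    params: np.ndarray
    names: list[str]
    vcov: np.ndarray  # phi * (X' W X)^{-1}
    dispersion: float  # Pearson phi
    loglik_poisson: float  # Poisson log-likelihood at the MLE
    n: int
    blocks: dict[str, slice] = field(default_factory=dict)
    converged: bool = True
    fitted_mean: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.params)

    @property
    def qaic(self) -> float:
        """QAIC with this model's own dispersion estimate."""
        return -2.0 * self.loglik_poisson / self.dispersion + 2.0 * self.p

    def block_params(self, block: str) -> np.ndarray:
        return self.params[self.blocks[block]]

    def block_vcov(self, block: str) -> np.ndarray:
        s = self.blocks[block]
        return self.vcov[s, s]

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov))
        return pd.DataFrame({"coef": self.params, "se": se}, index=self.names)


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    # pivoted QR flags the columns that enter the span last
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        _, _, piv = qr(design, mode="economic", pivoting=True)
        dependent = sorted(names[j] for j in piv[r:])
        raise ValueError(
            f"design matrix is rank deficient (rank {r} < {design.shape[1]}); "
            f"collinear columns: {dependent}"
        )


def fit_quasipoisson(
    y,
    design,
    names: list[str] | None = None,
    blocks: dict[str, slice] | None = None,
    offset=None,
    maxiter: int = 50,
    tol: float = 1e-9,
) -> FittedDlnm:
    """Fit a quasi-Poisson GLM with log link.

    ``y`` must be non-negative integers; ``design`` full column rank (an
    informative error names the collinear columns otherwise).  Convergence is
    relative deviance change below ``tol`` within ``maxiter`` IRLS
    iterations.
    """
    y = np.asarray(y, dtype=float).ravel()
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] != y.size:
        raise ValueError("design and outcome lengths disagree")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("outcome must be non-negative integer counts")
    if names is None:
        names = [f"x{j}" for j in range(design.shape[1])]
    _check_rank(design, names)

    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset)
    res = model.fit(scale="X2", maxiter=maxiter, tol=tol)
    if not res.converged:
        hist = getattr(res, "fit_history", {}).get("deviance", [])
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations; "
            f"deviance trace: {list(np.round(hist, 6))}"
        )
    mu = np.asarray(res.fittedvalues)
    fit = FittedDlnm(
        params=np.asarray(res.params),
        names=list(names),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        loglik_poisson=_poisson_loglik(y, mu),
        n=y.size,
        blocks=blocks or {},
        converged=True,
        fitted_mean=mu,
    )
    return fit


def assemble_design(
    cohort: pd.DataFrame,
    crossbases: dict[str, CrossBasis] | list[CrossBasis],
    covariates: list[str] | None = None,
    outcome: str = "y",
):
    """Outcome vector, design matrix and block map from cohort + cross-bases.

    Categorical covariates (object / category / bool dtype) are dummy-coded
    against their most frequent level; continuous covariates pass through
    unchanged.  Cross-basis blocks are appended after the covariates and
    their column spans recorded in the block map.

    Returns ``(y, design, names, blocks)`` with ``blocks`` mapping
    "intercept", each covariate, and each cross-basis name to a slice.
    """
    if isinstance(crossbases, list):
        crossbases = {f"cb{i + 1}": cb for i, cb in enumerate(crossbases)}
    n = len(cohort)
    for name, cb in crossbases.items():
        if cb.design.shape[0] != n:
            raise ValueError(f"cross-basis {name!r} rows do not match the cohort")
    y = cohort[outcome].to_numpy()

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    blocks: dict[str, slice] = {"intercept": slice(0, 1)}
    if covariates is None:
        covariates = []
    for cov in covariates:
        col = cohort[cov]
        start = len(names)
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            counts = col.value_counts()
            ref = counts.index[0]  # most frequent level is the reference
            levels = [lv for lv in counts.index if lv != ref]
            if col.isna().any():
                raise ValueError(f"covariate {cov!r} has missing values; impute first")
            for lv in sorted(levels, key=str):
                cols.append((col == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv} vs {ref}]")
        else:
            vals = col.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"covariate {cov!r} has missing values; impute first")
            cols.append(vals)
            names.append(cov)
        blocks[cov] = slice(start, len(names))
    for name, cb in crossbases.items():
        start = len(names)
        for j, k in cb.column_index:
            cols.append(cb.design[:, j * cb.spec.df_lag + k])
            names.append(f"{name}[v{j + 1}l{k + 1}]")
        blocks[name] = slice(start, len(names))
    design = np.column_stack(cols)
    return y, design, names, blocks


def fit_dlnm(
    cohort: pd.DataFrame,
    histories: dict,
    specs: dict,
    covariates: list[str] | None = None,
    outcome: str = "y",
) -> FittedDlnm:
    """Convenience wrapper: build cross-bases from histories + specs and fit."""
    cbs = {name: build_crossbasis(histories[name], specs[name]) for name in histories}
    y, design, names, blocks = assemble_design(cohort, cbs, covariates, outcome)
    return fit_quasipoisson(y, design, names, blocks)


def select_df(
    cohort: pd.DataFrame,
    histories: dict,
    candidates: list[tuple[int, int]],
    covariates: list[str] | None = None,
    outcome: str = "y",
):
    """Refit the model for each (df_var, df_lag) candidate and rank by QAIC.

    The dispersion used in QAIC is taken from the most complex candidate
    (largest parameter count) so candidates are compared on a common scale.
    Returns ``(chosen_specs, table)``: the specs dict of the minimizer and a
    DataFrame with one row per candidate (p, loglik, qaic; NaN where a fit
    failed) so the final choice can also weigh parsimony and visual
    inspection of the lag-response curves.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    fits: list[tuple[tuple[int, int], FittedDlnm | None]] = []
    for df_var, df_lag in candidates:
        specs = {
            name: spec_from_history(h, df_var=df_var, df_lag=df_lag)
            for name, h in histories.items()
        }
        try:
            fit = fit_dlnm(cohort, histories, specs, covariates, outcome)
        except (ValueError, RuntimeError):
            fit = None
        fits.append(((df_var, df_lag), fit))

    ok = [f for _, f in fits if f is not None]
    if not ok:
        raise RuntimeError("no candidate model could be fitted")
    phi_hat = max(ok, key=lambda f: f.p).dispersion

    rows = []
    for (df_var, df_lag), fit in fits:
        if fit is None:
            rows.append((df_var, df_lag, np.nan, np.nan, np.nan, np.nan))
        else:
            qaic = -2.0 * fit.loglik_poisson / phi_hat + 2.0 * fit.p
            rows.append(
                (df_var, df_lag, fit.p, fit.loglik_poisson, fit.dispersion, qaic)
            )
    table = pd.DataFrame(
        rows, columns=["df_var", "df_lag", "p", "loglik", "dispersion", "qaic"]
    )
    best = table["qaic"].idxmin()
    df_var, df_lag = int(table.loc[best, "df_var"]), int(table.loc[best, "df_lag"])
    chosen = {
        name: spec_from_history(h, df_var=df_var, df_lag=df_lag)
        for name, h in histories.items()
    }
    return chosen, table
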