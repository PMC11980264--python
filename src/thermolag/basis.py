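"""One-dimensional spline and linear bases.

The exposure-response and lag-response functions of a distributed-lag
non-linear model are each represented by a small one-dimensional basis:
either a natural cubic spline (linear beyond its boundary knots, so the
fitted curve is not dominated by the sparse tails of the exposure
distribution) or, for pollutants, a plain linear term.  Both bases omit the
intercept column — the model's own intercept absorbs the constant, and
omitting it keeps the tensor product of the two bases full rank.

Conventions:

* a natural cubic spline with ``df`` degrees of freedom carries ``df - 1``
  internal knots and contributes exactly ``df`` columns;
* internal knots sit at equally spaced quantiles of the data the basis is
  built from (linear interpolation between order statistics), boundary knots
  at the data minimum and maximum;
* the linear basis is the variable centred at the midpoint of its boundary
  knots, one column, ``df = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "place_knots", "eval_basis"]

NATURAL_CUBIC = "natural-cubic"
LINEAR = "linear"


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional basis.

    Parameters
    ----------
    kind : {"natural-cubic", "linear"}
    df : int
        Number of basis columns.  For the natural cubic spline this equals
        ``len(internal_knots) + 1``; for the linear kind it is 1.
    internal_knots : tuple of float
        Strictly increasing knots strictly inside the boundary knots.
        Empty for the linear kind.
    boundary_knots : tuple (lo, hi)
        Range over which the spline is cubic; beyond it the natural spline
        continues linearly (second derivative zero).
    """

    kind: str
    df: int
    internal_knots: tuple[float, ...] = field(default_factory=tuple)
    boundary_knots: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in (NATURAL_CUBIC, LINEAR):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        lo, hi = self.boundary_knots
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
            raise ValueError(
                f"boundary knots must be finite with lo < hi, got ({lo}, {hi})"
            )
        if self.kind == LINEAR:
            if self.df != 1:
                raise ValueError("linear basis must have df = 1")
            if self.internal_knots:
                raise ValueError("linear basis takes no internal knots")
        else:
            k = np.asarray(self.internal_knots, dtype=float)
            if k.size != self.df - 1:
                raise ValueError(
                    f"natural-cubic basis with df={self.df} needs "
                    f"{self.df - 1} internal knots, got {k.size}"
                )
            if k.size:
                if np.any(np.diff(k) <= 0):
                    raise ValueError("internal knots must be strictly increasing")
                if k[0] <= lo or k[-1] >= hi:
                    raise ValueError(
                        "internal knots must lie strictly inside the boundary knots"
                    )


def place_knots(values, df: int) -> BasisSpec:
    """Choose knots for a basis from the data it will be evaluated on.

    ``df = 1`` yields the linear basis (no knots).  ``df >= 2`` yields a
    natural cubic spline with ``df - 1`` internal knots at the
    ``1/df, 2/df, ...`` quantiles of ``values`` (linear interpolation), and
    boundary knots at the extremes.  For example ``df = 2`` places a single
    internal knot at the median.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot place knots on an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    if df < 1:
        raise ValueError("df must be a positive integer")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate range: all values identical")
    n_distinct = np.unique(values).size
    if df > n_distinct:
        raise ValueError(
            f"requested df={df} exceeds the number of distinct values ({n_distinct})"
        )
    if df == 1:
        return BasisSpec(LINEAR, 1, (), (lo, hi))
    probs = np.arange(1, df) / df
    internal = np.quantile(values, probs)  # linear interpolation rule
    if np.any(np.diff(internal) <= 0) or internal[0] <= lo or internal[-1] >= hi:
        raise ValueError(
            "quantile knots collide or touch the boundary; "
            "the data are too discrete for the requested df"
        )
    return BasisSpec(NATURAL_CUBIC, df, tuple(float(k) for k in internal), (lo, hi))


def _ns_transform(spec: BasisSpec):
    """Augmented knot vector, B-spline object and natural-constraint projector.

    The natural spline basis is obtained from the full cubic B-spline basis on
    the given knots by (i) dropping the first column, which removes the
    constant direction, and (ii) projecting onto the null space of the two
    second-derivative-at-boundary constraints via a QR decomposition.
    """
    lo, hi = spec.boundary_knots
    t = np.concatenate(([lo] * 4, spec.internal_knots, [hi] * 4))
    n_b = len(spec.internal_knots) + 4
    spl = BSpline(t, np.eye(n_b), 3, extrapolate=True)
    # two constraints: B''(lo) = B''(hi) = 0, intercept column removed first
    con = spl.derivative(2)(np.array([lo, hi]))[:, 1:]
    q, _ = np.linalg.qr(con.T, mode="complete")
    proj = q[:, 2:]  # (n_b - 1) x df
    return spl, proj


def eval_basis(spec: BasisSpec, x) -> np.ndarray:
    """Evaluate the basis at ``x``; returns a ``len(x) x spec.df`` matrix.

    Natural cubic splines are extended linearly beyond the boundary knots
    (second derivative identically zero there); the linear basis returns the
    centred variable.  Non-finite inputs raise, naming the first bad index.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value in x at index {bad[0]}")
    if spec.kind == LINEAR:
        center = 0.5 * (spec.boundary_knots[0] + spec.boundary_knots[1])
        return (x - center)[:, None]

    lo, hi = spec.boundary_knots
    spl, proj = _ns_transform(spec)
    inner = np.clip(x, lo, hi)
    b_full = spl(inner)
    below = x < lo
    above = x > hi
    if below.any() or above.any():
        # linear extension: value and slope taken at the nearer boundary
        for mask, edge in ((below, lo), (above, hi)):
            if mask.any():
                v = spl(np.array([edge]))[0]
                s = spl.derivative(1)(np.array([edge]))[0]
                b_full[mask] = v + (x[mask] - edge)[:, None] * s
    return b_full[:, 1:] @ proj


def check_extrapolation(spec: BasisSpec, x, context: str = "") -> None:
    """Warn (not raise) when values fall outside the basis boundary knots."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = spec.boundary_knots
    n_out = int(np.sum((x < lo) | (x > hi)))
    if n_out:
        warnings.warn(
            f"{context or 'basis evaluation'}: {n_out} value(s) outside the "
            f"boundary knots ({lo:g}, {hi:g}); the natural spline is "
            "extrapolated linearly there",
            stacklevel=3,
        )
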