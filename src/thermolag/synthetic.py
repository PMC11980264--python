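"""Synthetic birth-cohort generator with known ground truth.

Emulates the structure of a French national birth cohort: four enrollment
waves across one calendar year (early April, late June/early July, late
September/early October, late November/early December 2011), daily
temperature with metropolitan-France seasonal structure, a 0-100 word-count
outcome with median ≈ 81 (IQR ≈ 59-93) and mild overdispersion, and
optional MCAR covariate missingness.  The generating exposure-lag-response
surface is retained (:class:`SimulationTruth`) so parameter-recovery and
null-calibration tests can compare estimates to truth.

Daily temperature is an annual sinusoid (mean ≈ 12 °C, amplitude ≈ 8 °C,
summer peak) plus AR(1) weather noise (rho = 0.8, innovation SD 2.5 °C) and
a per-site offset; tmax/tmin add/subtract a seasonal diurnal half-range
floored at 0.5 °C.  Values are clamped to the observed metropolitan
envelopes so no simulated day is more extreme than the real record.

Outcomes are negative-binomial in the NB1 parameterisation: with
``alpha = phi - 1`` the count has mean ``mu`` and variance
``(1 + alpha) * mu = phi * mu`` at every mean — exactly the quasi-Poisson
variance function, so the Pearson dispersion of a correctly specified fit
estimates ``phi`` and model-based standard errors are consistent.  Scores
are truncated to [0, 100], mirroring the 100-word checklist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SimulationTruth",
    "null_truth",
    "postnatal_heat_hump_truth",
    "simulate_temperature",
    "simulate_cohort",
    "inject_missingness",
    "ENROLLMENT_WAVES",
]

# four 2011 enrollment windows (inclusive date ranges)
ENROLLMENT_WAVES = [
    ("2011-04-01", "2011-04-04"),
    ("2011-06-27", "2011-07-04"),
    ("2011-09-27", "2011-10-04"),
    ("2011-11-28", "2011-12-05"),
]

GESTATION_DAYS = 266  # conception -> birth
PRENATAL_DAYS = 30 * 7
POSTNATAL_DAYS = 91 * 7

# observed metropolitan envelopes (°C) used as physical clamps
TMEAN_RANGE = (-20.1, 31.8)
TMAX_RANGE = (-15.7, 42.8)
TMIN_RANGE = (-24.3, 29.1)

SEASON_MEAN = 12.0
SEASON_AMPLITUDE = 8.0
AR_RHO = 0.8
AR_SD = 2.5

# spatial structure across subjects: constant site offset + local AR(1)
# deviation of the subject's town from the national series
SITE_OFFSET_SD = 2.0
LOCAL_RHO = 0.8
LOCAL_SD = 2.0


@dataclass
class SimulationTruth:
    """Generating model: lag-response surfaces, covariate effects, dispersion.

    ``f_pre`` / ``f_post`` map (weekly temperature °C, lag week) to the
    log-rate contribution of that single week; both must vanish at the
    reference temperature so the baseline ``alpha0`` is interpretable.
    ``sex_modifier`` scales the temperature surfaces per sex, enabling
    sex-specific effect scenarios.
    """

    f_pre: Callable = None
    f_post: Callable = None
    alpha0: float = float(np.log(81.0))
    gamma: dict[str, dict] = field(default_factory=dict)
    dispersion_target: float = 1.5
    median_target: float = 81.0
    ref_temp: float = SEASON_MEAN
    sex_modifier: dict[str, float] = field(default_factory=lambda: {"M": 1.0, "F": 1.0})
    modality: str = "tmean"

    def __post_init__(self):
        zero = lambda x, lag: np.zeros_like(np.asarray(x, dtype=float))
        if self.f_pre is None:
            self.f_pre = zero
        if self.f_post is None:
            self.f_post = zero
        if self.dispersion_target <= 1.0:
            raise ValueError("dispersion_target must exceed 1 (overdispersion)")

    @property
    def nb1_alpha(self) -> float:
        """Overdispersion alpha of the NB1 law: Var = (1 + alpha) * mean.

        Clipping scores at the 100-word ceiling removes part of the
        generated excess dispersion, so the FITTED Pearson dispersion runs
        some 15% below ``dispersion_target``; generation nevertheless uses
        the nominal alpha, because compensating by inflating it would
        concentrate dispersion heterogeneity across the mean range (the
        ceiling caps the variance of high means) and distort model-based
        standard errors.
        """
        return self.dispersion_target - 1.0


def null_truth(**kw) -> SimulationTruth:
    """No temperature effect; covariate effects default at simulation time."""
    return SimulationTruth(**kw)


def postnatal_heat_hump_truth(
    peak_slope: float = 0.003,
    center: float = 14.5,
    width: float = 6.0,
    df_lag: int = 3,
    **kw,
) -> SimulationTruth:
    """Deleterious early-postnatal heat surface, linear in temperature.

    The per-week log-rate contribution is ``-slope(l) * (x - ref)``.  The
    lag profile is a Gaussian hump (peak ``peak_slope`` per °C at lag
    ``center``) projected onto the span of the postnatal natural-cubic lag
    basis with ``df_lag`` degrees of freedom, i.e. the surface is stored as
    a coefficient vector on a cross-basis and is exactly representable by
    the default analysis model — recovery tests then measure estimation
    error, not smoothing bias.  ``truth.true_support`` holds the inclusive
    lag range where the projected slope exceeds half its peak (the
    deleterious core of the surface); the cumulative effect of a sustained
    ~+10 °C contrast over that range is a relative risk around 0.75, the
    order of magnitude of reported multi-week postnatal heat windows.
    """
    from .basis import eval_basis, place_knots

    lags = np.arange(1, 92, dtype=float)
    c = eval_basis(place_knots(lags, df_lag), lags)
    target = peak_slope * np.exp(-(((lags - center) / width) ** 2))
    coef, *_ = np.linalg.lstsq(c, target, rcond=None)
    slope = c @ coef  # projected lag profile, length 91

    core = np.flatnonzero(slope > 0.5 * slope.max())
    truth = SimulationTruth(**kw)
    ref = truth.ref_temp

    def f_post(x, lag):
        lag_idx = np.asarray(lag, dtype=int) - 1
        return -slope[lag_idx] * (np.asarray(x, dtype=float) - ref)

    truth.f_post = f_post
    truth.lag_slope = slope
    truth.true_support = (int(core[0] + 1), int(core[-1] + 1))
    return truth


def true_cumulative_log_rr(
    truth: SimulationTruth, exposure: float, reference: float, lags
) -> float:
    """Ground-truth cumulative log-RR of the postnatal surface over ``lags``."""
    lags = np.asarray(lags, dtype=int)
    return float(
        np.sum(truth.f_post(np.full(lags.shape, exposure, dtype=float), lags))
        - np.sum(truth.f_post(np.full(lags.shape, reference, dtype=float), lags))
    )


def _seasonal(doy: np.ndarray) -> np.ndarray:
    # summer peak around mid-July (day ~197)
    return SEASON_MEAN + SEASON_AMPLITUDE * np.cos(2 * np.pi * (doy - 197.0) / 365.25)


def _ar1(n: int, rng: np.random.Generator, rho: float = AR_RHO, sd: float = AR_SD):
    out = np.empty(n)
    stat_sd = sd / np.sqrt(1.0 - rho**2)
    out[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov[t - 1]
    return out


def _daily_fields(dates: pd.DatetimeIndex, rng: np.random.Generator, site_offset=0.0):
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = len(dates)
    tmean = _seasonal(doy) + _ar1(n, rng) + site_offset
    # diurnal half-range: larger in summer, floored at 0.5 °C
    season = np.cos(2 * np.pi * (doy - 197.0) / 365.25)
    up = np.maximum(0.5, 5.0 + 1.5 * season + rng.normal(0.0, 1.0, n))
    down = np.maximum(0.5, 4.5 + 1.0 * season + rng.normal(0.0, 1.0, n))
    tmean = np.clip(tmean, *TMEAN_RANGE)
    tmax = np.clip(tmean + up, *TMAX_RANGE)
    tmin = np.clip(tmean - down, *TMIN_RANGE)
    tmax = np.maximum(tmax, tmean)  # clamps must not break the ordering
    tmin = np.minimum(tmin, tmean)
    return tmin, tmean, tmax


def _daily_pollutants(n: int, rng: np.random.Generator):
    pm25 = np.clip(np.exp(2.55 + _ar1(n, rng, 0.7, 0.35)), 0.0, 108.0)
    pm10 = np.clip(pm25 * 1.45 + rng.normal(0.0, 1.0, n), 0.0, 122.0)  # r > 0.9
    no2 = np.clip(np.exp(2.85 + _ar1(n, rng, 0.7, 0.35)), 0.0, 238.0)
    return pm25, pm10, no2


def simulate_temperature(
    start_date,
    n_days: int,
    site_offset: float = 0.0,
    seed: int | None = 0,
    subject_id="site",
    pollutants: bool = False,
) -> pd.DataFrame:
    """One daily environmental series as a DataFrame (subject_id, date, ...)."""
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    tmin, tmean, tmax = _daily_fields(dates, rng, site_offset)
    out = pd.DataFrame(
        {"subject_id": subject_id, "date": dates, "tmin": tmin, "tmean": tmean, "tmax": tmax}
    )
    if pollutants:
        out["pm25"], out["pm10"], out["no2"] = _daily_pollutants(n_days, rng)
    return out


_EDU_LEVELS = (["primary", "secondary", "tertiary"], [0.20, 0.45, 0.35])
_PARITY_LEVELS = (["0", "1", "2+"], [0.43, 0.35, 0.22])
_TERTILES = (["T1", "T2", "T3"], [1 / 3, 1 / 3, 1 / 3])

#: default covariate effects on the log mean.  The spread is deliberately
#: large (log-scale SD about 0.2, dominated by a strong low-education
#: deficit) so the marginal outcome distribution is wide and left-skewed —
#: median near 81 with lower quartile far below it — as vocabulary scores
#: at age two are; all of these covariates are observed and adjusted for,
#: so the conditional quasi-Poisson variance structure is untouched.
DEFAULT_GAMMA = {
    "sex": {"M": -0.04, "F": 0.04},
    "edu": {"primary": -0.25, "secondary": 0.0, "tertiary": 0.08},
    "parity": {"0": 0.03, "1": 0.0, "2+": -0.06},
    "deprivation": {"T1": 0.06, "T2": 0.0, "T3": -0.08},
    "age_test_months": 0.01,  # per month, centred at 25.5
}


def _covariate_lp(cohort: pd.DataFrame, gamma: dict) -> np.ndarray:
    lp = np.zeros(len(cohort))
    for cov, eff in gamma.items():
        if isinstance(eff, dict):
            lp += cohort[cov].map(eff).to_numpy(dtype=float)
        else:
            lp += eff * (cohort[cov].to_numpy(dtype=float) - 25.5)
    return lp


def simulate_cohort(
    n: int,
    truth: SimulationTruth | None = None,
    seed: int | None = 0,
    pollutants: bool = False,
    use_default_gamma: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table plus per-subject daily series.

    Birth dates are uniform within the four 2011 waves; conception is birth
    minus 266 days.  Every subject sees one shared regional weather
    realisation plus a constant site offset AND a local AR(1) deviation
    (their own town's weather relative to the national average): with a
    fixed gestation the prenatal and postnatal seasonal profiles are
    deterministic functions of the birth date, and only this spatial
    variation lets the model separate the two periods — exactly the role
    residential spread plays in a real national cohort.  Returns
    ``(cohort, daily)`` where ``daily`` covers conception − 7 days through
    birth + 637 days + 7 days for each subject.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    truth = truth or null_truth()
    rng = np.random.default_rng(seed)

    wave = rng.integers(0, len(ENROLLMENT_WAVES), size=n)
    starts = pd.to_datetime([ENROLLMENT_WAVES[w][0] for w in wave])
    lens = np.array(
        [
            (pd.Timestamp(b) - pd.Timestamp(a)).days + 1
            for a, b in ENROLLMENT_WAVES
        ]
    )
    birth = starts + pd.to_timedelta(rng.integers(0, lens[wave]), unit="D")
    conception = birth - pd.Timedelta(days=GESTATION_DAYS)

    # master regional weather covering every subject's span, one realisation
    m0 = conception.min() - pd.Timedelta(days=7)
    m1 = birth.max() + pd.Timedelta(days=POSTNATAL_DAYS + 7)
    master_dates = pd.date_range(m0, m1, freq="D")
    tmin_m, tmean_m, tmax_m = _daily_fields(master_dates, rng)
    site = rng.normal(0.0, SITE_OFFSET_SD, size=n)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"s{i:05d}" for i in range(n)],
            "sex": rng.choice(["M", "F"], size=n, p=[0.51, 0.49]),
            "edu": rng.choice(_EDU_LEVELS[0], size=n, p=_EDU_LEVELS[1]),
            "parity": rng.choice(_PARITY_LEVELS[0], size=n, p=_PARITY_LEVELS[1]),
            "deprivation": rng.choice(_TERTILES[0], size=n, p=_TERTILES[1]),
            "ndvi": rng.choice(_TERTILES[0], size=n, p=_TERTILES[1]),
            "age_test_months": np.round(rng.uniform(23.0, 28.0, size=n), 1),
            "conception_date": conception,
            "birth_date": birth,
        }
    )

    # per-subject local daily weather deviation over each subject's own span
    conc_idx = (conception - m0).days.to_numpy()
    birth_idx = (birth - m0).days.to_numpy()
    span = int((birth_idx - conc_idx).max() + POSTNATAL_DAYS + 15)
    from scipy.signal import lfilter

    innov = rng.normal(0.0, LOCAL_SD, size=(n, span))
    innov[:, 0] = rng.normal(0.0, LOCAL_SD / np.sqrt(1 - LOCAL_RHO**2), size=n)
    local = lfilter([1.0], [1.0, -LOCAL_RHO], innov, axis=1)

    # subject daily fields = national series + site offset + local deviation
    take_all = (conc_idx - 7)[:, None] + np.arange(span)
    spatial = site[:, None] + local
    subj_fields = {
        "tmin": tmin_m[take_all] + spatial,
        "tmean": tmean_m[take_all] + spatial,
        "tmax": tmax_m[take_all] + spatial,
    }

    # weekly exposure matrices of the truth's modality, exactly as the
    # pipeline's weekly averaging would compute them from the daily table
    subj_daily = subj_fields[truth.modality]
    pre_cols = 8 + np.arange(PRENATAL_DAYS)  # day conception+1 is column 8
    post_cols = (birth_idx - conc_idx + 8)[:, None] + np.arange(POSTNATAL_DAYS)
    x_pre = subj_daily[:, pre_cols].reshape(n, 30, 7).mean(axis=2)
    x_post = np.take_along_axis(subj_daily, post_cols, axis=1).reshape(n, 91, 7).mean(axis=2)

    mod = cohort["sex"].map(truth.sex_modifier).to_numpy(dtype=float)
    lags_pre = np.arange(1, 31, dtype=float)
    lags_post = np.arange(1, 92, dtype=float)
    lp_temp = mod * (
        truth.f_pre(x_pre, lags_pre[None, :]).sum(axis=1)
        + truth.f_post(x_post, lags_post[None, :]).sum(axis=1)
    )
    gamma = truth.gamma if (truth.gamma or not use_default_gamma) else DEFAULT_GAMMA
    lam = np.exp(truth.alpha0 + lp_temp + _covariate_lp(cohort, gamma))
    # NB1: size mu/alpha, success prob 1/(1+alpha) -> mean mu, var phi*mu
    alpha = truth.nb1_alpha
    y = rng.negative_binomial(lam / alpha, 1.0 / (1.0 + alpha))
    cohort["y"] = np.clip(y, 0, 100).astype(int)

    # per-subject daily series as a long-format table, identical values to
    # the matrices the outcome was generated from
    daily = pd.DataFrame(
        {
            "subject_id": np.repeat(cohort["subject_id"].to_numpy(), span),
            "date": (m0 + pd.to_timedelta(take_all.ravel(), unit="D")),
            "tmin": subj_fields["tmin"].ravel(),
            "tmean": subj_fields["tmean"].ravel(),
            "tmax": subj_fields["tmax"].ravel(),
        }
    )
    if pollutants:
        pm25_m, pm10_m, no2_m = _daily_pollutants(len(master_dates), rng)
        scale = np.exp(rng.normal(0.0, 0.1, size=n))
        daily["pm25"] = (pm25_m[take_all] * scale[:, None]).ravel()
        daily["pm10"] = (pm10_m[take_all] * scale[:, None]).ravel()
        daily["no2"] = (no2_m[take_all] * scale[:, None]).ravel()
    return cohort, daily


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mask covariate cells completely at random at the given per-column rates.

    The outcome and the anchor dates are never masked.
    """
    if mechanism != "MCAR":
        raise ValueError("only MCAR missingness is supported")
    protected = {"y", "subject_id", "conception_date", "birth_date"}
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col, rate in rates.items():
        if col in protected:
            raise ValueError(f"column {col!r} must not be masked")
        if not 0.0 <= rate < 1.0:
            raise ValueError("rates must lie in [0, 1)")
        mask = rng.random(len(out)) < rate
        s = out[col].copy()
        s[mask] = np.nan if s.dtype != object else None
        out[col] = s
    return out
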