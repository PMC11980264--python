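"""Weekly exposure histories aligned to conception and birth.

Daily environmental series (temperature in °C, pollutants in µg/m³) are
collapsed to subject × lag-week matrices: 30 gestational weeks counted from
the conception date for the prenatal period, 91 weeks counted from the birth
date for the postnatal period.  Week ``w`` (1-based) is the arithmetic mean
of days ``7(w-1)+1 .. 7w`` after the anchor, and every subject must have
complete daily coverage of the full span — partial weeks are an error, not
silently averaged.

Percentile contrasts for effect estimation are taken over the pooled
person-week values of a history: the reference is the pooled median, heat
contrasts use the upper percentiles (90/95/99) and cold contrasts the lower
ones (10/5/1), labelled moderate / severe / extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExposureHistory",
    "PRENATAL_WEEKS",
    "POSTNATAL_WEEKS",
    "SEVERITY_PERCENTILES",
    "read_daily_series",
    "build_history",
    "percentile_contrasts",
]

PRENATAL_WEEKS = 30
POSTNATAL_WEEKS = 91
_PERIOD_WEEKS = {"prenatal": PRENATAL_WEEKS, "postnatal": POSTNATAL_WEEKS}

#: severity -> (lower percentile, upper percentile), both contrasted vs the median
SEVERITY_PERCENTILES = {
    "moderate": (10, 90),
    "severe": (5, 95),
    "extreme": (1, 99),
}

MODALITIES = ("tmin", "tmean", "tmax", "pm25", "pm10", "no2")


@dataclass
class ExposureHistory:
    """Subject × lag-week matrix of one exposure modality for one period."""

    subjects: np.ndarray  # identifier vector, length n
    matrix: np.ndarray  # n x n_weeks weekly means, no missing cells
    modality: str
    period: str  # "prenatal" | "postnatal"

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = _PERIOD_WEEKS[self.period]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != expected:
            raise ValueError(
                f"{self.period} history must have {expected} weekly columns, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] != len(self.subjects):
            raise ValueError("subject vector and matrix rows disagree")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("exposure history contains missing cells")

    @property
    def n_weeks(self) -> int:
        return self.matrix.shape[1]

    def subset(self, mask_or_ids) -> "ExposureHistory":
        """Row subset (boolean mask over rows, or an iterable of subject ids)."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {s: i for i, s in enumerate(self.subjects)}
            idx = np.array([pos[s] for s in arr])
        return ExposureHistory(
            self.subjects[idx], self.matrix[idx], self.modality, self.period
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{w}" for w in range(1, self.n_weeks + 1)]
        out = pd.DataFrame(self.matrix, columns=cols)
        out.insert(0, "subject_id", self.subjects)
        return out


def read_daily_series(path) -> pd.DataFrame:
    """Read a daily series CSV (subject_id, date ISO-8601, tmin, tmean, ...)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"subject_id", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"daily series lacks required columns: {sorted(missing)}")
    return df


def build_history(
    series: pd.DataFrame,
    anchors: pd.Series,
    period: str,
    modality: str = "tmean",
) -> ExposureHistory:
    """Collapse a daily series into the fixed-length weekly history.

    Parameters
    ----------
    series : DataFrame with columns subject_id, date and the modality column.
    anchors : Series mapping subject_id -> anchor date (conception for
        prenatal, birth for postnatal).  Day 1 of week 1 is the day AFTER the
        anchor, i.e. days ``7(w-1)+1 .. 7w`` counted from the anchor.
    period : "prenatal" (30 weeks) or "postnatal" (91 weeks).
    modality : which measurement column to average.

    Raises if any subject lacks a day in the required span, listing the
    subject and the missing date range.
    """
    if period not in _PERIOD_WEEKS:
        raise ValueError(f"period must be prenatal or postnatal, got {period!r}")
    if modality not in series.columns:
        raise ValueError(f"daily series has no column {modality!r}")
    n_weeks = _PERIOD_WEEKS[period]
    span = 7 * n_weeks

    anchors = pd.Series(anchors)
    sub_ids = anchors.index.to_numpy()
    n = len(sub_ids)
    out = np.full((n, n_weeks), np.nan)

    dates = series["date"].to_numpy(dtype="datetime64[D]")
    values = series[modality].to_numpy(dtype=float)
    anchor_days = pd.DatetimeIndex(anchors.to_numpy()).values.astype("datetime64[D]")
    grouped = series.groupby("subject_id", sort=False).indices
    for i, sid in enumerate(sub_ids):
        if sid not in grouped:
            raise ValueError(f"subject {sid!r}: no daily data at all")
        rows = grouped[sid]
        # offset of each available day from the anchor; week 1 starts at day 1
        offs = (dates[rows] - anchor_days[i]).astype(int) - 1
        keep = (offs >= 0) & (offs < span)
        vals = np.full(span, np.nan)
        vals[offs[keep]] = values[rows[keep]]
        gaps = np.flatnonzero(~np.isfinite(vals))
        if gaps.size:
            start = anchor_days[i] + 1
            d0 = start + gaps[0]
            d1 = start + gaps[-1]
            raise ValueError(
                f"subject {sid!r}: {gaps.size} missing day(s) in required span "
                f"({d0} .. {d1}); {span} complete days from the anchor are needed"
            )
        out[i] = vals.reshape(n_weeks, 7).mean(axis=1)

    return ExposureHistory(sub_ids, out, modality, period)


def percentile_contrasts(history: ExposureHistory) -> dict:
    """Severity contrasts over the pooled person-week values of a history.

    Returns ``{"reference": median, "cold": {severity: (pct, value)},
    "heat": {severity: (pct, value)}}`` with percentiles computed by linear
    interpolation over every cell of the history matrix.
    """
    pooled = history.matrix.ravel()
    if pooled.size == 0:
        raise ValueError("empty exposure history")
    ref = float(np.percentile(pooled, 50))
    cold = {}
    heat = {}
    for severity, (p_lo, p_hi) in SEVERITY_PERCENTILES.items():
        cold[severity] = (p_lo, float(np.percentile(pooled, p_lo)))
        heat[severity] = (p_hi, float(np.percentile(pooled, p_hi)))
    return {"reference": ref, "cold": cold, "heat": heat}
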