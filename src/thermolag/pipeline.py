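"""End-to-end orchestration: impute -> histories -> cross-bases -> fit -> effects.

``run_main`` executes the unadjusted temperature analysis for one modality;
``run_adjusted`` adds prenatal and postnatal pollutant cross-bases (linear
exposure-response, 3 lag df) to estimate the temperature effect over and
above air pollution.  Requesting PM2.5 and PM10 together is refused — the
two are nearly collinear (daily correlation > 0.9) — unless explicitly
overridden.  Every run writes tidy CSVs plus a machine-readable
reproducibility log (config hash, seed, package versions) and is
deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossbasis import spec_from_history
from .effects import (
    cumulative_effect,
    effects_frame,
    find_windows,
    lag_effects,
    windows_frame,
)
from .exposure import build_history, percentile_contrasts
from .imputation import drop_high_missing, pmm_impute
from .model import fit_dlnm
from .strata import rrr_frame, stratified_analysis

__all__ = ["RunConfig", "run_main", "run_adjusted"]

DEFAULT_COVARIATES = ["sex", "edu", "parity", "deprivation", "ndvi", "age_test_months"]
POLLUTANTS = ("pm25", "pm10", "no2")


@dataclass
class RunConfig:
    cohort_csv: str | None = None
    daily_csv: str | None = None
    output_dir: str | None = None
    modality: str = "tmean"  # tmin | tmean | tmax
    pollutants: list[str] = field(default_factory=list)
    df_var: int = 2
    df_lag: int = 3
    pollutant_df_var: int = 1
    pollutant_df_lag: int = 3
    severities: list[str] = field(default_factory=lambda: ["moderate", "severe", "extreme"])
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    outcome: str = "y"
    seed: int = 0
    stratify_by_sex: bool = False
    allow_collinear_pm: bool = False
    impute: bool = True

    def __post_init__(self):
        bad = set(self.pollutants) - set(POLLUTANTS)
        if bad:
            raise ValueError(f"unknown pollutant(s): {sorted(bad)}")
        if {"pm25", "pm10"} <= set(self.pollutants) and not self.allow_collinear_pm:
            raise ValueError(
                "refusing to adjust for PM2.5 and PM10 together: the two are "
                "highly correlated (r > 0.9) and the joint model is nearly "
                "collinear; set allow_collinear_pm to override"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig, cohort=None, daily=None):
    if cohort is None:
        cohort = pd.read_csv(
            config.cohort_csv, parse_dates=["conception_date", "birth_date"]
        )
    if daily is None:
        daily = pd.read_csv(config.daily_csv, parse_dates=["date"])
    return cohort, daily


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

        return wrapped

    return deco


def _prepare_cohort(config: RunConfig, cohort: pd.DataFrame):
    cohort, report = drop_high_missing(cohort, config.covariates)
    if config.impute and cohort[config.covariates].isna().any().any():
        predictors = config.covariates + [config.outcome, "_mean_pre", "_mean_post"]
        cohort = pmm_impute(
            cohort,
            [c for c in config.covariates if cohort[c].isna().any()],
            predictors,
            seed=config.seed,
        )
    return cohort, report


def _build_block(daily, cohort, modality, period, anchor_col, df_var, df_lag):
    anchors = pd.Series(
        cohort[anchor_col].to_numpy(), index=cohort["subject_id"].to_numpy()
    )
    hist = build_history(daily, anchors, period, modality)
    spec = spec_from_history(hist, df_var=df_var, df_lag=df_lag)
    return hist, spec


def run_main(config: RunConfig, cohort=None, daily=None) -> dict:
    """Unadjusted temperature analysis (heat and cold, all severities).

    ``cohort``/``daily`` may be passed in memory; otherwise they are read
    from the paths in the config.  Returns a result bundle dict; if
    ``config.output_dir`` is set the tables and the reproducibility log are
    written there too.
    """
    return _run(config, cohort, daily, adjusted=False)


def run_adjusted(config: RunConfig, cohort=None, daily=None) -> dict:
    """Pollutant-adjusted temperature analysis (direct effect)."""
    if not config.pollutants:
        raise ValueError("run_adjusted needs at least one pollutant in the config")
    return _run(config, cohort, daily, adjusted=True)


def _run(config: RunConfig, cohort, daily, adjusted: bool) -> dict:
    cohort, daily = _stage("load")(_load_inputs)(config, cohort, daily)
    if adjusted:
        missing = [p for p in config.pollutants if p not in daily.columns]
        if missing:
            raise RuntimeError(
                f"pipeline stage 'load' failed: daily series lacks pollutant "
                f"column(s) {missing}"
            )

    # mean exposures enter the imputation model, as covariate predictors do
    def add_mean_exposures(cohort):
        anchors_c = pd.Series(
            cohort["conception_date"].to_numpy(), index=cohort["subject_id"].to_numpy()
        )
        anchors_b = pd.Series(
            cohort["birth_date"].to_numpy(), index=cohort["subject_id"].to_numpy()
        )
        pre = build_history(daily, anchors_c, "prenatal", config.modality)
        post = build_history(daily, anchors_b, "postnatal", config.modality)
        cohort = cohort.copy()
        cohort["_mean_pre"] = pre.matrix.mean(axis=1)
        cohort["_mean_post"] = post.matrix.mean(axis=1)
        return cohort, pre, post

    cohort, pre_hist_all, post_hist_all = _stage("exposure")(add_mean_exposures)(cohort)
    cohort, miss_report = _stage("missingness")(_prepare_cohort)(config, cohort)

    keep = cohort["subject_id"].to_numpy()
    histories = {
        "temp_pre": pre_hist_all.subset(keep),
        "temp_post": post_hist_all.subset(keep),
    }
    specs = {
        name: spec_from_history(h, df_var=config.df_var, df_lag=config.df_lag)
        for name, h in histories.items()
    }
    if adjusted:
        for pol in config.pollutants:
            for period, anchor, tag in (
                ("prenatal", "conception_date", "pre"),
                ("postnatal", "birth_date", "post"),
            ):
                h, s = _stage("pollutant-exposure")(_build_block)(
                    daily, cohort, pol, period, anchor,
                    config.pollutant_df_var, config.pollutant_df_lag,
                )
                histories[f"{pol}_{tag}"] = h
                specs[f"{pol}_{tag}"] = s

    fit = _stage("fit")(fit_dlnm)(
        cohort, histories, specs, config.covariates, config.outcome
    )

    all_effects = []
    all_windows = []
    contrast_table = []
    for name in ("temp_pre", "temp_post"):
        hist, spec = histories[name], specs[name]
        ctr = percentile_contrasts(hist)
        for side in ("cold", "heat"):
            for severity in config.severities:
                pct, value = ctr[side][severity]
                label = f"{side}:{severity}"
                ests = lag_effects(
                    fit, spec, name, value, ctr["reference"],
                    period=hist.period, modality=config.modality, severity=label,
                )
                cum_fn = lambda lags, _s=spec, _n=name, _v=value, _r=ctr["reference"]: (
                    cumulative_effect(
                        fit, _s, _n, _v, _r, lags,
                        period=hist.period, modality=config.modality, severity=label,
                    )
                )
                wins = find_windows(ests, cumulative_fn=cum_fn)
                all_effects.extend(ests)
                all_windows.extend(wins)
                contrast_table.append(
                    {
                        "period": hist.period,
                        "side": side,
                        "severity": severity,
                        "percentile": pct,
                        "exposure_value": value,
                        "reference": ctr["reference"],
                    }
                )

    result = {
        "config": config,
        "fit": fit,
        "histories": histories,
        "specs": specs,
        "contrasts": pd.DataFrame(contrast_table),
        "effects": effects_frame(all_effects),
        "windows": windows_frame(all_windows),
        "missingness": miss_report,
        "adjusted": adjusted,
    }

    if config.stratify_by_sex:
        strata_contrasts = {}
        for name in ("temp_pre", "temp_post"):
            ctr = percentile_contrasts(histories[name])
            strata_contrasts[name] = {
                "exposure": ctr["heat"]["severe"][1],
                "reference": ctr["reference"],
            }
        temp_specs = {k: specs[k] for k in ("temp_pre", "temp_post")}
        temp_hists = {k: histories[k] for k in ("temp_pre", "temp_post")}
        result["stratified"] = _stage("stratify")(stratified_analysis)(
            cohort, temp_hists, temp_specs, strata_contrasts,
            config.covariates, config.outcome,
        )

    if config.output_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: dict) -> None:
    config: RunConfig = result["config"]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["effects"].to_csv(out / "effects.csv", index=False)
    result["windows"].to_csv(out / "windows.csv", index=False)
    result["contrasts"].to_csv(out / "contrasts.csv", index=False)
    result["fit"].coef_table().to_csv(out / "coefficients.csv")
    if "stratified" in result:
        strat = result["stratified"]
        for name, series in strat["rrr_per_lag"].items():
            rrr_frame(series).to_csv(out / f"rrr_{name}.csv", index=False)
        wins = []
        for lv in strat["strata"]:
            for name, blk in strat["per_stratum"][lv]["blocks"].items():
                wf = windows_frame(blk["windows"])
                wf.insert(0, "stratum", lv)
                wf.insert(1, "block", name)
                wins.append(wf)
        pd.concat(wins, ignore_index=True).to_csv(
            out / "windows_by_stratum.csv", index=False
        )
    log = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_digest": config.digest(),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_fitted": result["fit"].n,
        "dispersion": result["fit"].dispersion,
        "qaic": result["fit"].qaic,
        "missingness": result["missingness"].to_dict(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
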