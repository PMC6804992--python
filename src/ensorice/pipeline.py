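"""The seven-step workflow wired together behind a single run configuration.

Phase 1 (crop-model side): (1) calibrate the surrogate on plot
experiments, (2) validate it against the provincial yield panel with
Nash-Sutcliffe efficiency, (3) project 2020-2050 seasonal yields under
RCP deltas.  Phase 2 (impact side): (4) estimate historical ENSO
reduction ratios, (5) classify them into provincial levels, (6) read the
risk-area fractions, (7) account future production per province and for
the whole delta.

Every step takes the validated :class:`RunConfig` plus in-memory outputs
of earlier steps and writes its table(s) into the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import fixtures
from .calendars import EnsoCalendar
from .config import AnomalyConfig, ScenarioDelta
from .crop_surrogate import CalibrationResult, SurrogateParams, calibrate
from .enso_reduction import classify_levels, estimate_reductions, reduction_cdf
from .io import SCHEMAS, read_table, write_table
from .production_accounting import build_report, derive_demo_areas, production_table
from .scenario_projection import project_yields, summarize_changes
from .seasons import MRD_PROVINCES, SEASONS_BY_PROVINCE, Season
from .synthetic_data import generate_plot_experiments, generate_yield_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_all"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    seed: int
    provinces: tuple[str, ...] = MRD_PROVINCES
    historical_years: tuple[int, int] = (1976, 2016)
    future_years: tuple[int, int] = (2020, 2050)
    baseline_years: tuple[int, int] = (2005, 2016)
    scenarios: tuple[str, ...] = ("RCP4.5", "RCP8.5")
    reduction_truth: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ElNino": 20.0, "LaNina": 12.0}
    )
    noise_sd: float = 0.1
    pest_years: tuple[tuple[int, str], ...] = ((1992, "AW"), (2002, "AW"), (2009, "AW"))
    pest_depression_pct: float = 30.0
    plots_per_season: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"WS": 8, "SA": 7, "AW": 4}
    )
    plot_noise_sd: float = 0.0
    min_years_ef: int = 5
    surrogate: Mapping[str, float] = dataclasses.field(default_factory=dict)
    calibration_free: tuple[str, ...] = (
        "potential_yield",
        "heat_sensitivity",
        "water_sensitivity",
    )
    calibration_bounds: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "potential_yield": (3.0, 12.0),
            "heat_sensitivity": (0.0, 2.0),
            "water_sensitivity": (0.0, 1.0),
        }
    )
    risk_areas_path: str | None = None  # None -> packaged table

    def surrogate_params(self) -> SurrogateParams:
        return SurrogateParams(**self.surrogate)


_KNOWN_KEYS = {
    "seed", "provinces", "historical_years", "future_years", "baseline_years",
    "scenarios", "reduction_truth", "noise_sd", "pest_years",
    "pest_depression_pct", "plots_per_season", "plot_noise_sd", "min_years_ef",
    "surrogate", "calibration", "risk_areas_path",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError(f"{path}: an explicit seed is required")
    kwargs: dict = {"seed": int(raw["seed"])}
    if "provinces" in raw:
        p = raw["provinces"]
        kwargs["provinces"] = MRD_PROVINCES if p == "mrd13" else tuple(p)
    for key in ("historical_years", "future_years", "baseline_years"):
        if key in raw:
            lo, hi = raw[key]
            kwargs[key] = (int(lo), int(hi))
    if "scenarios" in raw:
        kwargs["scenarios"] = tuple(raw["scenarios"])
    if "reduction_truth" in raw:
        kwargs["reduction_truth"] = {str(k): float(v) for k, v in raw["reduction_truth"].items()}
    for key in ("noise_sd", "pest_depression_pct", "plot_noise_sd"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "pest_years" in raw:
        kwargs["pest_years"] = tuple((int(y), str(s)) for y, s in raw["pest_years"])
    if "plots_per_season" in raw:
        kwargs["plots_per_season"] = {str(k): int(v) for k, v in raw["plots_per_season"].items()}
    if "min_years_ef" in raw:
        kwargs["min_years_ef"] = int(raw["min_years_ef"])
    if "surrogate" in raw:
        kwargs["surrogate"] = {str(k): v for k, v in raw["surrogate"].items()}
    if "calibration" in raw:
        cal = raw["calibration"]
        extra = set(cal) - {"free", "bounds"}
        if extra:
            raise ConfigError(f"{path}: unknown calibration keys {sorted(extra)}")
        if "free" in cal:
            kwargs["calibration_free"] = tuple(cal["free"])
        if "bounds" in cal:
            kwargs["calibration_bounds"] = {
                str(k): (float(lo), float(hi)) for k, (lo, hi) in cal["bounds"].items()
            }
    if "risk_areas_path" in raw and raw["risk_areas_path"] is not None:
        kwargs["risk_areas_path"] = str(raw["risk_areas_path"])
    return RunConfig(**kwargs)


def step_calibrate(cfg: RunConfig, outdir: Path) -> dict[Season, CalibrationResult]:
    """Step 1: per-season surrogate calibration on synthetic plot experiments."""
    truth = cfg.surrogate_params()
    plots = generate_plot_experiments(
        cfg.plots_per_season, truth, noise_sd=cfg.plot_noise_sd, seed=cfg.seed
    )
    results: dict[Season, CalibrationResult] = {}
    reports = []
    summaries = []
    for season in Season:
        season_plots = [p for p in plots if p.season is season]
        if len(season_plots) < 3:
            logger.warning("season %s has %d plots; skipped", season.value, len(season_plots))
            continue
        res = calibrate(
            season_plots,
            initial=truth.replace(
                potential_yield=truth.potential_yield * 0.8,
                heat_sensitivity=min(truth.heat_sensitivity * 1.5, 2.0),
            ),
            bounds=cfg.calibration_bounds,
            free=cfg.calibration_free,
        )
        results[season] = res
        reports.append(res.report)
        summaries.append(
            {"season": season.value, "n": len(season_plots),
             "rmse": res.rmse, "r_squared": res.r_squared}
        )
    write_table(pd.concat(reports, ignore_index=True), outdir / "calibration_report.csv")
    write_table(pd.DataFrame(summaries), outdir / "calibration_summary.csv")
    return results


def step_validate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Step 2: historical panel generation + Nash-Sutcliffe validation report."""
    from .validation_stats import validation_report

    calendar = fixtures.load_historical_calendar()
    panel, truth = generate_yield_panel(
        cfg.provinces,
        cfg.historical_years,
        calendar,
        cfg.reduction_truth,
        pest_years=cfg.pest_years,
        pest_depression_pct=cfg.pest_depression_pct,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    write_table(panel, outdir / "yield_panel.csv", SCHEMAS["yield_panel"])
    write_table(truth, outdir / "reduction_truth.csv")
    report = validation_report(panel, min_years=cfg.min_years_ef)
    write_table(report, outdir / "validation_report.csv")
    return panel


def step_reduce(cfg: RunConfig, panel: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    """Steps 4-5: reduction estimates, CDFs and level classification."""
    calendar = fixtures.load_historical_calendar()
    estimates = estimate_reductions(panel, calendar, exclusions=cfg.pest_years)
    write_table(estimates, outdir / "reduction_estimates.csv")
    cdf_rows = []
    level_rows = []
    for (province, season), grp in estimates.groupby(["province", "season"], sort=False):
        if season == Season.SA.value:
            continue
        cdf = reduction_cdf(grp["d"])
        cdf.insert(0, "season", season)
        cdf.insert(0, "province", province)
        cdf_rows.append(cdf)
        levels = classify_levels(grp["d"])
        levels.insert(0, "phase", "ElNino" if season == "WS" else "LaNina")
        levels.insert(0, "province", province)
        level_rows.append(levels)
    write_table(pd.concat(cdf_rows, ignore_index=True), outdir / "reduction_cdfs.csv")
    level_table = pd.concat(level_rows, ignore_index=True)
    write_table(
        level_table[["province", "phase", "level", "d_lower", "d_upper", "d"]],
        outdir / "reduction_levels_estimated.csv",
        SCHEMAS["reduction_levels"],
    )
    return level_table


def step_project(
    cfg: RunConfig, calibrated: Mapping[Season, CalibrationResult], outdir: Path
) -> pd.DataFrame:
    """Step 3 + change summary: baseline and scenario yield projection."""
    params_by_cell = {
        (province, season): calibrated[season].params
        for province in cfg.provinces
        for season in SEASONS_BY_PROVINCE.get(province, tuple(Season))
        if season in calibrated
    }
    baseline = project_yields(
        params_by_cell, ScenarioDelta.null(), cfg.baseline_years, seed=cfg.seed
    )
    futures = [
        project_yields(
            params_by_cell,
            fixtures.load_scenario_delta(name),
            cfg.future_years,
            seed=cfg.seed,
        )
        for name in cfg.scenarios
    ]
    future = pd.concat(futures, ignore_index=True)
    write_table(
        pd.concat([baseline, future], ignore_index=True), outdir / "projected_yields.csv"
    )
    changes = summarize_changes(baseline, future)
    write_table(changes, outdir / "yield_changes_projected.csv")
    return changes


def step_account(
    cfg: RunConfig, changes: pd.DataFrame, level_table: pd.DataFrame, outdir: Path
) -> pd.DataFrame:
    """Steps 6-7: risk areas + production accounting report."""
    provincial = changes[changes["province"] != "Regional average"]
    present_yields = (
        provincial[provincial["scenario"] == cfg.scenarios[0]]
        .rename(columns={"present": "yield"})[["province", "season", "yield"]]
        .reset_index(drop=True)
    )
    future_yields = provincial.rename(columns={"future": "yield"})[
        ["province", "scenario", "season", "yield"]
    ].reset_index(drop=True)
    if cfg.risk_areas_path:
        risk = read_table(cfg.risk_areas_path, SCHEMAS["risk_areas"])
    else:
        risk = fixtures.load_risk_areas()
    missing = [p for p in cfg.provinces if p not in set(risk["province"])]
    if missing:
        raise KeyError(f"provinces missing from risk-area table: {missing}")
    production_ref, _ = fixtures.load_production()
    production_ref = production_ref[production_ref["province"].isin(cfg.provinces)]
    areas = derive_demo_areas(production_ref, present_yields)
    write_table(areas, outdir / "areas_demo.csv", SCHEMAS["areas"])
    report = build_report(
        present_yields,
        future_yields,
        level_table[["province", "phase", "level", "d"]],
        risk,
        areas,
        scenarios=cfg.scenarios,
    )
    write_table(report, outdir / "production_long.csv")
    table = production_table(report)
    table.index.name = "province"
    table.round(2).to_csv(outdir / "production_report.csv")
    return report


def run_all(cfg: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute steps 1-7 in order, writing all tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calibrated = step_calibrate(cfg, outdir)
    panel = step_validate(cfg, outdir)
    level_table = step_reduce(cfg, panel, outdir)
    changes = step_project(cfg, calibrated, outdir)
    report = step_account(cfg, changes, level_table, outdir)
    return {
        "panel": panel,
        "levels": level_table,
        "changes": changes,
        "report": report,
    }
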