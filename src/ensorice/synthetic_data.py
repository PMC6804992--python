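"""Synthetic inputs for the whole pipeline: weather, yield panels, plots, risk tables.

The generators emulate the statistical structure of the delta's data so
every downstream stage is testable without external downloads:

* daily weather follows a stationary tropical-monsoon climatology with
  the documented El Nino (+1 degC, +30 sunshine h/month, +25 mm/month
  evaporation) and La Nina (+80 mm/month rainfall) anomalies applied
  inside the December-April window of tagged years, and RCP scenario
  deltas applied additively (temperature) / multiplicatively (rainfall);
* provincial yield panels carry a smooth trend, ENSO-year depressions at
  a known true reduction ratio, and separate pest-outbreak depressions,
  with the truth table returned alongside for recovery tests;
* plot-level calibration experiments are surrogate output plus noise;
* risk-area tables are random rows of four fractions summing to 100%.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calendars import EnsoCalendar
from .config import AnomalyConfig, ScenarioDelta
from .crop_surrogate import SurrogateParams, extract_season, simulate_yield
from .seasons import (
    HAZARD_SEASON,
    MRD_PROVINCES,
    SEASONS_BY_PROVINCE,
    Phase,
    Season,
)

__all__ = [
    "Climatology",
    "PlotExperiment",
    "generate_weather",
    "generate_yield_panel",
    "generate_risk_table",
    "generate_plot_experiments",
]

#: Pest/disease outbreak seasons the delta's yield record shows outside
#: ENSO influence (brown plant hopper / grassy stunt virus).
DEFAULT_PEST_YEARS: frozenset[tuple[int, Season]] = frozenset(
    {(1992, Season.AW), (2002, Season.AW), (2009, Season.AW)}
)


@dataclass(frozen=True)
class Climatology:
    """Monthly neutral-year climatology of a delta province.

    Values loosely match a tropical monsoon regime: a weak annual
    temperature cycle around 27 degC, a pronounced May-November wet
    season, and a dry, sunny December-April.  Index 0 = January.
    """

    tmean: tuple[float, ...] = (25.5, 26.5, 27.8, 28.9, 28.6, 27.9,
                                27.5, 27.4, 27.2, 27.0, 26.6, 25.6)
    rain_mm_month: tuple[float, ...] = (10.0, 5.0, 15.0, 50.0, 180.0, 220.0,
                                        230.0, 230.0, 270.0, 270.0, 130.0, 40.0)
    sunshine_h_day: tuple[float, ...] = (8.5, 8.8, 8.9, 8.3, 6.5, 5.8,
                                         5.9, 5.6, 5.3, 5.9, 7.0, 7.8)
    humidity_pct: tuple[float, ...] = (80.0, 78.0, 77.0, 78.0, 83.0, 85.0,
                                       85.0, 86.0, 87.0, 86.0, 84.0, 81.0)
    evap_mm_day: tuple[float, ...] = (3.8, 4.3, 4.8, 4.6, 3.6, 3.3,
                                      3.3, 3.2, 3.0, 3.1, 3.3, 3.5)
    temp_sd: float = 0.8       # day-to-day sd of mean temperature, degC
    diurnal_range: float = 8.0  # typical tmax - tmin, degC
    sunshine_sd: float = 1.0
    humidity_sd: float = 3.0
    evap_sd: float = 0.5
    wind_mean: float = 2.0      # m/s
    wind_sd: float = 0.8
    rain_shape: float = 0.4     # gamma shape of daily rainfall


def _province_rng(seed: int, province: str, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, province, purpose)."""
    tag = zlib.crc32(f"{stream}:{province}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def generate_weather(
    province: str,
    year_range: tuple[int, int],
    scenario_delta: ScenarioDelta | None = None,
    enso_calendar: EnsoCalendar | None = None,
    anomaly: AnomalyConfig | None = None,
    seed: int = 0,
    climatology: Climatology | None = None,
) -> pd.DataFrame:
    """Daily weather for one province over ``year_range`` (inclusive).

    The random draws depend only on ``(seed, province, year_range)``;
    ENSO anomalies and scenario deltas are deterministic transforms of
    those draws, so scenarios are exactly paired and a null delta is
    bitwise-identical to the baseline.
    """
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise ValueError("year_range must be non-empty (start <= end)")
    clim = climatology or Climatology()
    anomaly = anomaly or AnomalyConfig()
    calendar = enso_calendar or EnsoCalendar()

    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    month = dates.month.to_numpy()
    year = dates.year.to_numpy()
    dim = dates.days_in_month.to_numpy().astype(float)
    n = len(dates)
    m = month - 1

    rng = _province_rng(seed, province, f"weather:{y0}:{y1}")
    # Fixed draw order keeps scenario/ENSO variants exactly paired.
    e_t = rng.normal(0.0, clim.temp_sd, n)
    e_up = np.abs(rng.normal(0.0, 0.5, n))
    e_dn = np.abs(rng.normal(0.0, 0.5, n))
    g_rain = rng.gamma(clim.rain_shape, 1.0, n)          # unit-scale gamma
    e_sun = rng.normal(0.0, clim.sunshine_sd, n)
    e_hum = rng.normal(0.0, clim.humidity_sd, n)
    e_wind = np.abs(rng.normal(clim.wind_mean, clim.wind_sd, n))
    e_evap = rng.normal(0.0, clim.evap_sd, n)

    # Per-day ENSO anomaly masks from the calendar's tagged years.
    in_window = np.isin(month, list(anomaly.months))
    phase_by_year = {y: calendar.phase_of_year(y) for y in np.unique(year)}
    phase_code = np.array([phase_by_year[y].value for y in year])
    nino = in_window & (phase_code == Phase.EL_NINO.value)
    nina = in_window & (phase_code == Phase.LA_NINA.value)

    dT_scen = scenario_delta.dT if scenario_delta is not None else 0.0
    rain_fac = (
        scenario_delta.rain_factor(province) if scenario_delta is not None else 1.0
    )

    tmean = np.asarray(clim.tmean)[m] + e_t + dT_scen + anomaly.elnino_dT * nino
    tmax = tmean + clim.diurnal_range / 2 + e_up
    tmin = tmean - clim.diurnal_range / 2 - e_dn

    rain_mean = np.asarray(clim.rain_mm_month)[m] / dim * rain_fac
    rain_mean = rain_mean + anomaly.lanina_dRain / dim * nina
    rainfall = g_rain * (rain_mean / clim.rain_shape)

    sunshine = np.asarray(clim.sunshine_h_day)[m] + e_sun
    sunshine = sunshine + anomaly.elnino_dSunshine / dim * nino
    sunshine = np.clip(sunshine, 0.0, 14.0)

    humidity = np.clip(np.asarray(clim.humidity_pct)[m] + e_hum, 0.0, 100.0)
    evap = np.maximum(np.asarray(clim.evap_mm_day)[m] + e_evap, 0.0)
    evap = evap + anomaly.elnino_dEvap / dim * nino

    return pd.DataFrame(
        {
            "province": province,
            "date": dates,
            "tmax": tmax,
            "tmin": tmin,
            "tmean": tmean,
            "rainfall": rainfall,
            "sunshine": sunshine,
            "humidity": humidity,
            "wind": e_wind,
            "evap": evap,
        }
    )


#: Default season-mean observed yields (ton/ha) anchoring panel trends.
DEFAULT_BASE_YIELDS: dict[Season, float] = {
    Season.WS: 6.0,
    Season.SA: 4.7,
    Season.AW: 4.3,
}


def _truth_lookup(reduction_truth, province: str, season: Season, phase: Phase) -> float:
    """Normalise the several accepted shapes of a reduction-truth argument."""
    if isinstance(reduction_truth, (int, float)):
        return float(reduction_truth)
    if isinstance(reduction_truth, Mapping):
        for key in (
            (province, season, phase),
            (province, season.value, phase.value),
            (phase, ),
            phase,
            phase.value,
        ):
            if not isinstance(key, tuple):
                if key in reduction_truth:
                    return float(reduction_truth[key])
            elif key in reduction_truth:
                return float(reduction_truth[key])
        raise KeyError(
            f"reduction_truth has no entry for {province}/{season.value}/{phase.value}"
        )
    raise TypeError("reduction_truth must be a number or a mapping")


def generate_yield_panel(
    provinces: Sequence[str],
    year_range: tuple[int, int],
    enso_calendar: EnsoCalendar,
    reduction_truth,
    pest_years: Iterable[tuple[int, Season | str]] = (),
    pest_depression_pct: float = 30.0,
    noise_sd: float = 0.1,
    base_yields: Mapping[Season, float] | None = None,
    trend_slope: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed/simulated provincial yield panel with known ENSO truth.

    The stress-free simulated yield YS follows a linear trend; observed
    yield YO equals YS depressed by the true reduction ratio in tagged
    ENSO hazard seasons, by ``pest_depression_pct`` in pest-outbreak
    seasons, plus additive N(0, noise_sd) noise.  Returns
    ``(panel, truth)`` where ``truth`` lists the true D per province x
    hazard season x phase for recovery tests.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    y0, y1 = int(year_range[0]), int(year_range[1])
    base = dict(DEFAULT_BASE_YIELDS)
    if base_yields:
        base.update({Season(k): float(v) for k, v in base_yields.items()})
    pest = {(int(y), Season(s)) for y, s in pest_years}

    records = []
    truth_rows = []
    for pi, province in enumerate(provinces):
        rng = _province_rng(seed, province, "panel")
        offset = 0.3 * (pi % 5 - 2)  # spread provincial levels a little
        for season in SEASONS_BY_PROVINCE.get(province, tuple(Season)):
            for phase in (Phase.EL_NINO, Phase.LA_NINA):
                if HAZARD_SEASON[phase] is season:
                    truth_rows.append(
                        {
                            "province": province,
                            "season": season.value,
                            "phase": phase.value,
                            "d_true": _truth_lookup(reduction_truth, province, season, phase),
                        }
                    )
            for year in range(y0, y1 + 1):
                ys = base[season] + offset + trend_slope * (year - y0)
                phase = enso_calendar.phase_of(year, season)
                factor = 1.0
                if phase is not Phase.NEUTRAL and HAZARD_SEASON[phase] is season:
                    d = _truth_lookup(reduction_truth, province, season, phase)
                    factor *= 1.0 - d / 100.0
                if (year, season) in pest:
                    factor *= 1.0 - pest_depression_pct / 100.0
                yo = max(ys * factor + rng.normal(0.0, noise_sd), 0.0) if noise_sd else ys * factor
                records.append(
                    {
                        "province": province,
                        "season": season.value,
                        "year": year,
                        "yo": yo,
                        "ys": ys,
                    }
                )
    panel = pd.DataFrame.from_records(records)
    truth = pd.DataFrame.from_records(truth_rows)
    return panel, truth


def generate_risk_table(provinces: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Random risk-area table: four fractions per province x hazard, summing to 100."""
    if not len(provinces):
        raise ValueError("provinces must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7269736B]))
    rows = []
    for province in provinces:
        for hazard in ("salinity", "flood"):
            frac = rng.dirichlet([2.0, 2.0, 2.0, 4.0]) * 100.0
            frac = np.round(frac, 1)
            frac[-1] = round(100.0 - frac[:-1].sum(), 1)
            rows.append(
                {
                    "province": province,
                    "hazard": hazard,
                    "high": frac[0],
                    "medium": frac[1],
                    "low": frac[2],
                    "none": frac[3],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlotExperiment:
    """One plot-level calibration experiment (season weather + harvested yield)."""

    plot_id: int
    season: Season
    weather: pd.DataFrame
    yo_plot: float
    management: Mapping[str, object] = field(default_factory=dict)


DEFAULT_PLOT_COUNTS: dict[Season, int] = {Season.WS: 8, Season.SA: 7, Season.AW: 4}


def generate_plot_experiments(
    n_plots_per_season: Mapping[Season | str, int] | None = None,
    true_params: SurrogateParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    climatology: Climatology | None = None,
) -> list[PlotExperiment]:
    """Plot experiments whose yields are surrogate output plus noise.

    Plots within a season differ through management perturbations — a
    sowing-date temperature offset and an irrigation/rainfall multiplier
    — recorded in ``management``, giving the calibration problem enough
    contrast to identify the stress sensitivities.
    """
    counts = {Season(k): int(v) for k, v in (n_plots_per_season or DEFAULT_PLOT_COUNTS).items()}
    if any(v < 1 for v in counts.values()):
        raise ValueError("need at least one plot per requested season")
    params = true_params or SurrogateParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x706C6F74]))
    base = generate_weather(
        "Soc Trang", (2011, 2013), seed=seed, climatology=climatology
    )
    plots: list[PlotExperiment] = []
    for season, n in counts.items():
        season_wx = extract_season(base, season, 2012).reset_index(drop=True)
        for i in range(n):
            dt = rng.uniform(-1.0, 3.0)
            water_mult = rng.uniform(0.3, 1.2)
            wx = season_wx.copy()
            for col in ("tmax", "tmin", "tmean"):
                wx[col] = wx[col] + dt
            wx["rainfall"] = wx["rainfall"] * water_mult
            yo = simulate_yield(wx, params)
            if noise_sd:
                yo += rng.normal(0.0, noise_sd)
            plots.append(
                PlotExperiment(
                    plot_id=i + 1,
                    season=season,
                    weather=wx,
                    yo_plot=max(float(yo), 0.01),
                    management={
                        "sowing_temp_offset": float(dt),
                        "water_multiplier": float(water_mult),
                        "fertilizer_events": ({"day": 20, "kg_n_ha": 40},
                                              {"day": 45, "kg_n_ha": 30}),
                    },
                )
            )
    return plots
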