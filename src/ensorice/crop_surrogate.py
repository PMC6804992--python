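"""A minimal weather-driven rice-yield simulator with a calibration routine.

This module is explicitly NOT ORYZA.  ORYZA is a full eco-physiological
crop model (phenology, nitrogen, soil water balance); here a deliberately
small surrogate maps seasonal weather to yield through two multiplicative
stress factors, so the calibrate -> validate -> project workflow is
executable and analytically testable end-to-end.  The surrogate sits
behind a one-function interface (:func:`simulate_yield`), so a coupling
to a full crop model could replace it without touching the pipeline.

Model
-----
Let ``Tbar`` be the mean daily temperature and ``R`` the total rainfall
over the first ``season_length`` days of the season.  With parameters
``y*`` (potential yield), ``T_opt``, ``s_T`` (ton/ha per degC above
optimum), ``W`` (seasonal water requirement, mm) and ``s_W`` in [0, 1]:

    heat factor   f_T = clip(1 - s_T * max(0, Tbar - T_opt) / y*, 0, 1)
    water factor  f_W = clip(1 - s_W * max(0, (W - R) / W),      0, 1)
    yield         YS  = y* * f_T * f_W

Both factors lie in [0, 1]; stress can never raise the yield, and a
stress-free season returns exactly the potential yield.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .seasons import Season, season_window

__all__ = [
    "SurrogateParams",
    "CalibrationResult",
    "simulate_yield",
    "yield_from_stats",
    "extract_season",
    "calibrate",
]


class SeasonTooShortError(ValueError):
    """Season weather does not cover the crop's growing window."""


class CalibrationError(ValueError):
    """Ill-posed calibration request (unbounded space, non-finite loss...)."""


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate yield response.

    Units: potential_yield ton/ha; t_opt degC; heat_sensitivity ton/ha
    per degC above optimum; water_requirement mm/season;
    water_sensitivity dimensionless in [0, 1]; season_length days
    (local varieties mature in 95-110 days).
    """

    potential_yield: float = 7.0
    t_opt: float = 28.0
    heat_sensitivity: float = 0.6
    water_requirement: float = 400.0
    water_sensitivity: float = 0.7
    season_length: int = 100

    def __post_init__(self) -> None:
        if self.potential_yield <= 0:
            raise ValueError("potential_yield must be positive")
        if not (95 <= self.season_length <= 110):
            raise ValueError("season_length must lie in [95, 110] days")
        if self.heat_sensitivity < 0 or self.water_sensitivity < 0:
            raise ValueError("sensitivities must be non-negative")
        if self.water_sensitivity > 1:
            raise ValueError("water_sensitivity must lie in [0, 1]")
        if self.water_requirement <= 0:
            raise ValueError("water_requirement must be positive")

    def replace(self, **kwargs) -> "SurrogateParams":
        return dataclasses.replace(self, **kwargs)


def yield_from_stats(tbar, rain, params: SurrogateParams):
    """Yield from season aggregates (vectorised core of the surrogate)."""
    tbar = np.asarray(tbar, dtype=float)
    rain = np.asarray(rain, dtype=float)
    heat = np.clip(
        1.0
        - params.heat_sensitivity
        * np.maximum(0.0, tbar - params.t_opt)
        / params.potential_yield,
        0.0,
        1.0,
    )
    water = np.clip(
        1.0
        - params.water_sensitivity
        * np.maximum(0.0, (params.water_requirement - rain) / params.water_requirement),
        0.0,
        1.0,
    )
    out = params.potential_yield * heat * water
    return float(out) if out.ndim == 0 else out


def simulate_yield(season_weather: pd.DataFrame, params: SurrogateParams) -> float:
    """Simulated seasonal yield (YS, ton/ha) from daily season weather.

    Uses the first ``params.season_length`` days of the supplied window.
    Raises :class:`SeasonTooShortError` if the window is shorter.
    """
    n = len(season_weather)
    if n < params.season_length:
        raise SeasonTooShortError(
            f"season weather has {n} days, need {params.season_length}"
        )
    head = season_weather.iloc[: params.season_length]
    return yield_from_stats(head["tmean"].mean(), head["rainfall"].sum(), params)


def extract_season(weather: pd.DataFrame, season: Season | str, year: int) -> pd.DataFrame:
    """Slice one cropping season (labelled by harvest year) out of a daily series."""
    start, end = season_window(season, year)
    d = pd.to_datetime(weather["date"])
    return weather.loc[(d >= pd.Timestamp(start)) & (d <= pd.Timestamp(end))]


@dataclass(frozen=True)
class CalibrationResult:
    params: SurrogateParams
    rmse: float
    r_squared: float
    report: pd.DataFrame  # per-plot: plot, season, yo, ys, residual


_CALIBRATABLE = (
    "potential_yield",
    "t_opt",
    "heat_sensitivity",
    "water_requirement",
    "water_sensitivity",
)


def calibrate(
    plots: Sequence,
    initial: SurrogateParams,
    bounds: Mapping[str, tuple[float, float]],
    free: Iterable[str] = ("potential_yield", "heat_sensitivity", "water_sensitivity"),
) -> CalibrationResult:
    """Fit surrogate parameters to plot experiments by least squares.

    ``plots`` are objects with ``plot_id``, ``season``, ``weather`` and
    ``yo_plot`` attributes (see :mod:`ensorice.synthetic_data`).  Only the
    parameters named in ``free`` are adjusted; every free parameter needs
    a finite (lo, hi) pair in ``bounds``.  The fit minimises the RMSE
    between observed and simulated plot yields and is deterministic for
    a fixed ``initial`` starting point.
    """
    free = tuple(free)
    for name in free:
        if name not in _CALIBRATABLE:
            raise CalibrationError(f"parameter {name!r} is not calibratable")
        if name not in bounds:
            raise CalibrationError(f"no bounds given for free parameter {name!r}")
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise CalibrationError(f"bounds for {name!r} must be finite with lo < hi")
    if not free:
        raise CalibrationError("no free parameters to calibrate")

    counts: dict[str, int] = {}
    for p in plots:
        counts[str(Season(p.season).value)] = counts.get(str(Season(p.season).value), 0) + 1
    thin = {s: c for s, c in counts.items() if c < 3}
    if not counts or thin:
        raise CalibrationError(
            f"need >= 3 plots per calibrated season, got {counts or 'none'}"
        )

    L = initial.season_length
    tbar = np.array([p.weather["tmean"].iloc[:L].mean() for p in plots])
    rain = np.array([p.weather["rainfall"].iloc[:L].sum() for p in plots])
    yo = np.array([float(p.yo_plot) for p in plots])

    def with_theta(theta: np.ndarray) -> SurrogateParams:
        return initial.replace(**dict(zip(free, (float(t) for t in theta))))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return yo - yield_from_stats(tbar, rain, with_theta(theta))

    x0 = np.array([getattr(initial, name) for name in free], dtype=float)
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    x0 = np.clip(x0, lo, hi)
    r0 = residuals(x0)
    if not np.all(np.isfinite(r0)):
        raise CalibrationError("non-finite objective at the starting point")

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    fitted = with_theta(sol.x)
    ys = yield_from_stats(tbar, rain, fitted)
    rmse = float(np.sqrt(np.mean((yo - ys) ** 2)))
    if len(yo) >= 2 and np.std(yo) > 0 and np.std(ys) > 0:
        r2 = float(stats.pearsonr(yo, ys)[0] ** 2)
    else:
        r2 = float("nan")
    report = pd.DataFrame(
        {
            "plot": [p.plot_id for p in plots],
            "season": [Season(p.season).value for p in plots],
            "yo": yo,
            "ys": ys,
            "residual": yo - ys,
        }
    )
    return CalibrationResult(params=fitted, rmse=rmse, r_squared=r2, report=report)
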