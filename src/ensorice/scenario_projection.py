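"""Future yield projection under RCP scenario deltas, and change ratios.

Projected seasonal yields for 2020-2050 come from running the calibrated
crop surrogate on scenario-shifted synthetic weather, holding farming
conditions fixed at their baseline state.  ENSO depressions are *not*
applied here; they are layered on downstream from the historical
reduction levels.  The present-vs-future comparison is summarised by the
change ratio

    D = 100 * (present_mean - future_mean) / present_mean  (%)

and by unweighted regional averages over the provinces cropping a season.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioDelta
from .crop_surrogate import SurrogateParams, yield_from_stats
from .seasons import Season, season_window
from .synthetic_data import Climatology, generate_weather

__all__ = [
    "project_yields",
    "change_ratio",
    "regional_average",
    "summarize_changes",
    "MissingParamsError",
]


class MissingParamsError(KeyError):
    """Calibrated parameters are missing for requested province x season cells."""


def _season_aggregates(weather: pd.DataFrame, season: Season, years: range, length: int):
    """Mean temperature and total rainfall of each season-year, vectorised."""
    dates = pd.DatetimeIndex(weather["date"])
    tmean = weather["tmean"].to_numpy()
    rain = weather["rainfall"].to_numpy()
    tbar = np.empty(len(years))
    rtot = np.empty(len(years))
    for i, year in enumerate(years):
        start, _ = season_window(season, year)
        j = dates.searchsorted(pd.Timestamp(start))
        k = j + length
        if k > len(dates):
            raise ValueError(f"weather series ends before {season.value} {year} completes")
        tbar[i] = tmean[j:k].mean()
        rtot[i] = rain[j:k].sum()
    return tbar, rtot


def project_yields(
    params_by_cell: Mapping[tuple[str, Season | str], SurrogateParams],
    delta: ScenarioDelta,
    year_range: tuple[int, int] = (2020, 2050),
    cells: Sequence[tuple[str, Season | str]] | None = None,
    seed: int = 0,
    climatology: Climatology | None = None,
) -> pd.DataFrame:
    """Simulated seasonal yields per province x season x year x scenario.

    ``params_by_cell`` maps (province, season) to calibrated surrogate
    parameters; only listed cells are simulated (a province without a
    winter-spring crop simply has no WS entry).  Requesting a cell with
    no parameters raises :class:`MissingParamsError` listing the cells.
    Weather draws depend on the seed but not on the scenario, so
    scenarios are exactly paired and a null delta reproduces the
    baseline bitwise.
    """
    params = {(p, Season(s)): v for (p, s), v in params_by_cell.items()}
    want = (
        [(p, Season(s)) for p, s in cells]
        if cells is not None
        else sorted(params, key=lambda c: (c[0], c[1].value))
    )
    missing = [c for c in want if c not in params]
    if missing:
        raise MissingParamsError(
            "no calibrated parameters for: "
            + ", ".join(f"{p}/{s.value}" for p, s in missing)
        )
    y0, y1 = int(year_range[0]), int(year_range[1])
    years = range(y0, y1 + 1)
    rows = []
    for province in dict.fromkeys(p for p, _ in want):  # stable unique order
        weather = generate_weather(
            province,
            (y0 - 1, y1),
            scenario_delta=delta,
            seed=seed,
            climatology=climatology,
        )
        for p, season in want:
            if p != province:
                continue
            prm = params[(p, season)]
            tbar, rain = _season_aggregates(weather, season, years, prm.season_length)
            ys = yield_from_stats(tbar, rain, prm)
            for year, y in zip(years, ys):
                rows.append(
                    {
                        "province": province,
                        "season": season.value,
                        "year": year,
                        "scenario": delta.name,
                        "ys": float(y),
                    }
                )
    return pd.DataFrame(rows)


def change_ratio(present_mean: float, future_mean: float) -> float:
    """Percent yield change D = 100 (present - future) / present."""
    present_mean = float(present_mean)
    if present_mean <= 0:
        raise ValueError("present mean yield must be positive")
    return 100.0 * (present_mean - float(future_mean)) / present_mean


def regional_average(values) -> float:
    """Unweighted arithmetic mean over provinces cropping the season."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("regional average of zero provinces")
    return float(arr.mean())


def summarize_changes(
    present_panel: pd.DataFrame, future_panel: pd.DataFrame
) -> pd.DataFrame:
    """Present vs future mean yields and change ratios per cell.

    Both panels are long tables with province/season/year/ys columns;
    the future panel additionally carries a scenario column.  Regional
    rows (province = "Regional average") are unweighted province means.
    """
    present = (
        present_panel.groupby(["province", "season"])["ys"].mean().rename("present")
    )
    future = (
        future_panel.groupby(["province", "scenario", "season"])["ys"]
        .mean()
        .rename("future")
    )
    table = future.reset_index().join(present, on=["province", "season"])
    table["d_pct"] = [
        change_ratio(p, f) for p, f in zip(table["present"], table["future"])
    ]
    regional = (
        table.groupby(["scenario", "season"])[["present", "future", "d_pct"]]
        .mean()
        .reset_index()
    )
    regional.insert(0, "province", "Regional average")
    out = pd.concat([table, regional], ignore_index=True)
    return out[["province", "scenario", "season", "present", "future", "d_pct"]]
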