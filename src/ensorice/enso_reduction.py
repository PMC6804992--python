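"""Historical ENSO yield-reduction ratios: estimation, distribution, levels.

The reduction ratio of an ENSO hazard season is the percent shortfall of
the observed yield relative to the stress-free simulated yield,

    D = (YS - YO) / YS * 100,  clamped to [0, 100],

positive when ENSO damage pulls the observed crop below its simulated
potential.  Ratios estimated over the historical record are summarised
as empirical cumulative distributions and classified into
province-specific low / medium / high levels; the level's D is then
applied to future simulated yields as YF = YS * (1 - D/100).

The summer-autumn season faces neither salinity intrusion nor flooding,
so its reduction is identically zero.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .calendars import EnsoCalendar
from .seasons import HAZARD_SEASON, Phase, Season

__all__ = [
    "yield_reduction",
    "estimate_reductions",
    "reduction_cdf",
    "classify_levels",
    "apply_reduction",
    "DEFAULT_EXCLUSIONS",
]

logger = logging.getLogger(__name__)

#: Pest-outbreak seasons excluded from ENSO attribution by default.
DEFAULT_EXCLUSIONS: frozenset[tuple[int, Season]] = frozenset(
    {(1992, Season.AW), (2002, Season.AW), (2009, Season.AW)}
)

LEVELS = ("high", "medium", "low")


class UnknownLevelError(KeyError):
    pass


def yield_reduction(yo: float, ys: float) -> float:
    """Percent yield shortfall D relative to the simulated potential."""
    yo_a = np.asarray(yo, dtype=float)
    ys_a = np.asarray(ys, dtype=float)
    if np.any(ys_a <= 0):
        raise ValueError("simulated yield must be positive to define a reduction ratio")
    if np.any(yo_a < 0):
        raise ValueError("observed yield must be non-negative")
    d = np.clip((ys_a - yo_a) / ys_a * 100.0, 0.0, 100.0)
    return float(d) if d.ndim == 0 else d


def estimate_reductions(
    panel: pd.DataFrame,
    calendar: EnsoCalendar,
    exclusions: Iterable[tuple[int, Season | str]] = DEFAULT_EXCLUSIONS,
) -> pd.DataFrame:
    """One reduction estimate per province x hazard season x ENSO year.

    Pest-outbreak seasons in ``exclusions`` are skipped (their yield dips
    are not ENSO damage); panel cells missing either yield are skipped
    with a logged warning.  For every ENSO year the summer-autumn season
    is emitted with D = 0, since it faces neither hazard.
    """
    excluded = {(int(y), Season(s)) for y, s in exclusions}
    provinces = panel["province"].unique()
    indexed = panel.set_index(["province", "season", "year"]).sort_index()
    rows = []
    for year, phase, season in calendar:
        if (year, season) in excluded:
            continue
        for province in provinces:
            for s, d_forced in ((season, None), (Season.SA, 0.0)):
                try:
                    cell = indexed.loc[(province, s.value, year)]
                except KeyError:
                    if d_forced is None:
                        logger.warning(
                            "no panel cell for %s %s %d; skipped", province, s.value, year
                        )
                    continue
                yo, ys = float(cell["yo"]), float(cell["ys"])
                if d_forced is not None:
                    d = d_forced
                elif not np.isfinite(yo) or not np.isfinite(ys) or ys <= 0:
                    logger.warning(
                        "missing yield for %s %s %d; skipped", province, s.value, year
                    )
                    continue
                else:
                    d = yield_reduction(yo, ys)
                rows.append(
                    {
                        "province": province,
                        "season": s.value,
                        "year": year,
                        "phase": phase.value,
                        "d": d,
                    }
                )
    return pd.DataFrame(rows, columns=["province", "season", "year", "phase", "d"])


def reduction_cdf(estimates) -> pd.DataFrame:
    """Empirical CDF of reduction estimates for one province x season.

    Returns the sorted unique D values with cumulative probabilities;
    the last row's D is the severe-year (maximum observed) reduction.
    """
    d = np.sort(np.asarray(estimates, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("cannot build a CDF from zero estimates")
    values, counts = np.unique(d, return_counts=True)
    return pd.DataFrame(
        {"d": values, "cum_prob": np.cumsum(counts) / d.size}
    )


def _tertiles(d_sorted: np.ndarray) -> list[np.ndarray]:
    return [g for g in np.array_split(d_sorted, 3)]


def classify_levels(estimates, rule=None) -> pd.DataFrame:
    """Classify reduction estimates into low / medium / high bands.

    The default rule splits the positive estimates into empirical
    tertiles; each band's representative D is its maximum (so the high
    level carries the worst observed year).  With fewer than three
    distinct positive estimates the output degenerates to a single band
    repeated for all three levels.

    Returns rows ``level, d_lower, d_upper, d`` ordered high, medium, low.
    """
    d = np.asarray(estimates, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("cannot classify zero estimates")
    pos = np.sort(d[d > 0])
    if pos.size < 3 or np.unique(pos).size < 3:
        val = float(pos.max()) if pos.size else 0.0
        lo = float(pos.min()) if pos.size else 0.0
        return pd.DataFrame(
            [{"level": lv, "d_lower": lo, "d_upper": val, "d": val} for lv in LEVELS]
        )
    groups = (rule or _tertiles)(pos)
    if len(groups) != 3 or any(len(g) == 0 for g in groups):
        raise ValueError("classification rule must produce three non-empty bands")
    low, medium, high = groups
    rows = []
    for lv, grp in zip(LEVELS, (high, medium, low)):
        rows.append(
            {
                "level": lv,
                "d_lower": float(np.min(grp)),
                "d_upper": float(np.max(grp)),
                "d": float(np.max(grp)),
            }
        )
    return pd.DataFrame(rows)


def apply_reduction(ys: float, level: str, table: pd.DataFrame) -> float:
    """Future yield YF = YS * (1 - D/100) for the given reduction level."""
    match = table.loc[table["level"] == level, "d"]
    if match.empty:
        raise UnknownLevelError(f"no reduction entry for level {level!r}")
    d = float(match.iloc[0])
    if not 0.0 <= d <= 100.0:
        raise ValueError(f"reduction D={d} outside [0, 100]")
    if ys < 0:
        raise ValueError("simulated yield must be non-negative")
    return float(ys) * (1.0 - d / 100.0)
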