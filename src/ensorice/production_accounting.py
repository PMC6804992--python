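"""Risk-area-weighted rice production accounting.

Seasonal production of a province sums yield x area over the risk
strata,

    PPs = sum_l YF_{s,l} * S_{s,l}        (tons),

annual production sums the province's applicable seasons,

    PPa = sum_s PPs,

and the regional (MRD) total sums the 13 provinces.  In the ENSO
columns each stratum's future yield is depressed by the reduction level
matching its mapped risk level (high-risk land takes the high-level D,
and the no-risk stratum is never reduced); El Nino reductions hit the
winter-spring crop through the salinity strata, La Nina the
autumn-winter crop through the flood strata.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enso_reduction import UnknownLevelError
from .seasons import MRD_PROVINCES, Season

__all__ = [
    "seasonal_production",
    "annual_production",
    "mrd_total",
    "loss_percent",
    "build_report",
    "production_table",
    "derive_demo_areas",
]

STRATA = ("high", "medium", "low", "none")
#: Identity mapping from a stratum's risk level to the reduction level it takes.
DEFAULT_STRATUM_LEVELS: dict[str, str] = {"high": "high", "medium": "medium", "low": "low"}

CONDITIONS = ("present", "no_enso", "elnino", "lanina")
_PHASE_SEASON_HAZARD = {"elnino": (Season.WS, "salinity"), "lanina": (Season.AW, "flood")}


class StrataError(ValueError):
    pass


class MissingProvinceError(KeyError):
    pass


def seasonal_production(
    yf_by_level: Mapping[str, float], area_by_level: Mapping[str, float]
) -> float:
    """PPs (tons) = sum over strata of yield (ton/ha) x area (ha)."""
    if set(yf_by_level) != set(area_by_level):
        raise StrataError(
            f"strata mismatch: yields {sorted(yf_by_level)} vs areas {sorted(area_by_level)}"
        )
    total = 0.0
    for level, yf in yf_by_level.items():
        area = float(area_by_level[level])
        if area < 0:
            raise StrataError(f"negative area for stratum {level!r}")
        total += float(yf) * area
    return total


def annual_production(seasonal: Mapping | Iterable[float]) -> float:
    """PPa (tons) over the province's applicable seasons (absent != zero)."""
    values = list(seasonal.values()) if isinstance(seasonal, Mapping) else list(seasonal)
    if not values:
        raise ValueError("a province needs at least one cropping season")
    return float(np.sum(values))


def mrd_total(
    ppa_by_province: Mapping[str, float],
    required: Sequence[str] = MRD_PROVINCES,
) -> float:
    """Regional total over all 13 provinces; missing provinces are an error."""
    missing = [p for p in required if p not in ppa_by_province]
    if missing:
        raise MissingProvinceError(f"provinces missing from total: {missing}")
    return float(np.sum([ppa_by_province[p] for p in required]))


def loss_percent(present: float, condition: float) -> float:
    """Percent production lost relative to the present level."""
    present = float(present)
    if present <= 0:
        raise ValueError("present production must be positive")
    return 100.0 * (present - float(condition)) / present


def _stratified_production(
    yield_tha: float,
    area_ha: float,
    fractions: Mapping[str, float],
    level_d: Mapping[str, float],
    stratum_levels: Mapping[str, str],
) -> float:
    """Season production with per-stratum reductions applied."""
    yf = {}
    areas = {}
    for stratum in STRATA:
        d = 0.0
        if stratum != "none":
            level = stratum_levels.get(stratum)
            if level is not None and level_d:
                if level not in level_d:
                    raise UnknownLevelError(f"no reduction D for level {level!r}")
                d = float(level_d[level])
        yf[stratum] = yield_tha * (1.0 - d / 100.0)
        areas[stratum] = area_ha * float(fractions[stratum]) / 100.0
    return seasonal_production(yf, areas)


def build_report(
    present_yields: pd.DataFrame,
    future_yields: pd.DataFrame,
    level_table: pd.DataFrame,
    risk_areas: pd.DataFrame,
    areas: pd.DataFrame,
    scenarios: Sequence[str] = ("RCP4.5", "RCP8.5"),
    stratum_levels: Mapping[str, str] = DEFAULT_STRATUM_LEVELS,
) -> pd.DataFrame:
    """Table-6-shaped production accounting in long form.

    Inputs (all long tables): ``present_yields`` province/season/yield
    (ton/ha); ``future_yields`` province/scenario/season/yield;
    ``level_table`` province/phase/level/d; ``risk_areas``
    province/hazard/high/medium/low/none fractions (%); ``areas``
    province/season/area_ha.  Returns rows
    ``province, scenario, condition, production_t`` where condition is
    present, no_enso, elnino or lanina.  A province absent from any
    input table raises :class:`MissingProvinceError`.
    """
    provinces = list(dict.fromkeys(present_yields["province"]))
    for name, table in (
        ("future_yields", future_yields),
        ("risk_areas", risk_areas),
        ("areas", areas),
    ):
        have = set(table["province"])
        missing = [p for p in provinces if p not in have]
        if missing:
            raise MissingProvinceError(f"provinces missing from {name}: {missing}")

    y_present = present_yields.set_index(["province", "season"])["yield"]
    y_future = future_yields.set_index(["province", "scenario", "season"])["yield"]
    area = areas.set_index(["province", "season"])["area_ha"]
    risk = risk_areas.set_index(["province", "hazard"])

    def level_d(province: str, phase: str) -> dict[str, float]:
        rows = level_table[
            (level_table["province"] == province) & (level_table["phase"] == phase)
        ]
        return dict(zip(rows["level"], rows["d"].astype(float)))

    def seasons_of(province: str) -> list[str]:
        return [s for (p, s) in y_present.index if p == province]

    records = []
    for province in provinces:
        seasons = seasons_of(province)
        pp_present = {
            s: y_present[(province, s)] * area[(province, s)] for s in seasons
        }
        records.append(
            {
                "province": province,
                "scenario": "present",
                "condition": "present",
                "production_t": annual_production(pp_present),
            }
        )
        for scenario in scenarios:
            pp_future = {
                s: y_future[(province, scenario, s)] * area[(province, s)]
                for s in seasons
            }
            records.append(
                {
                    "province": province,
                    "scenario": scenario,
                    "condition": "no_enso",
                    "production_t": annual_production(pp_future),
                }
            )
            for condition, (season, hazard) in _PHASE_SEASON_HAZARD.items():
                pp = dict(pp_future)
                s = season.value
                if s in seasons:
                    phase = "ElNino" if condition == "elnino" else "LaNina"
                    d_map = level_d(province, phase)
                    fractions = risk.loc[(province, hazard)]
                    pp[s] = _stratified_production(
                        float(y_future[(province, scenario, s)]),
                        float(area[(province, s)]),
                        fractions,
                        d_map,
                        stratum_levels,
                    )
                records.append(
                    {
                        "province": province,
                        "scenario": scenario,
                        "condition": condition,
                        "production_t": annual_production(pp),
                    }
                )
    return pd.DataFrame.from_records(records)


def production_table(report: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Pivot the long report to the printed layout, in units of ``scale`` tons.

    Adds the MRD total row and a rice-lost (%) row computed from the
    unrounded regional totals.
    """
    wide = pd.DataFrame(index=list(dict.fromkeys(report["province"])))
    cols = [("present", "present")] + [
        (sc, cond)
        for sc in ("RCP4.5", "RCP8.5")
        for cond in ("no_enso",)
    ] + [
        (sc, cond)
        for sc in ("RCP4.5", "RCP8.5")
        for cond in ("elnino", "lanina")
    ]
    for scenario, condition in cols:
        sub = report[
            (report["scenario"] == scenario) & (report["condition"] == condition)
        ].set_index("province")["production_t"]
        label = "present" if condition == "present" else f"{scenario} {condition}"
        wide[label] = sub / scale
    totals = wide.sum(axis=0)
    losses = {
        c: loss_percent(totals["present"], totals[c]) for c in wide.columns if c != "present"
    }
    wide.loc["MRD"] = totals
    wide.loc["Rice lost (%)"] = pd.Series({"present": np.nan, **losses})
    return wide


def derive_demo_areas(
    production: pd.DataFrame, present_yields: pd.DataFrame
) -> pd.DataFrame:
    """Synthetic per-province rice areas consistent with printed totals.

    The absolute cultivated areas S (ha) are not public alongside the
    production table, so the demo back-derives one area per province —
    annual production divided by the sum of its present seasonal yields
    — and uses it for every applicable season.  This is a demo
    convenience that reproduces the present production column exactly;
    it is synthetic, not survey data.
    """
    y_sum = present_yields.groupby("province")["yield"].sum()
    rows = []
    for _, row in production.iterrows():
        province = row["province"]
        if province not in y_sum.index:
            raise MissingProvinceError(f"no present yields for {province!r}")
        area = float(row["present"]) * 1e6 / float(y_sum[province])
        for season in present_yields.loc[
            present_yields["province"] == province, "season"
        ]:
            rows.append({"province": province, "season": season, "area_ha": area})
    return pd.DataFrame(rows)
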