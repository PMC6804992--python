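"""Loaders for the packaged reference tables and default configuration.

The package ships small CSV mirrors of the printed reference tables —
risk-area fractions, plot-level calibration yields, reduction-level
bands, present/future yield comparisons, production totals — plus the
future ENSO calendar, an approximate (user-replaceable) historical ENSO
calendar, and default RCP scenario deltas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calendars import EnsoCalendar
from .config import ScenarioDelta
from .io import SCHEMAS, validate_table

__all__ = [
    "load_risk_areas",
    "load_plot_yields",
    "load_reduction_levels",
    "load_yield_changes",
    "load_production",
    "load_future_calendar",
    "load_historical_calendar",
    "load_scenario_deltas",
    "load_scenario_delta",
]


def _load(name: str, schema_key: str) -> pd.DataFrame:
    with resources.files("ensorice.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    return validate_table(df, SCHEMAS[schema_key])


def load_risk_areas() -> pd.DataFrame:
    """Province x hazard fractions of rice land at each risk level (%)."""
    return _load("risk_areas.csv", "risk_areas")


def load_plot_yields() -> pd.DataFrame:
    """Plot-level observed/simulated yields of the calibration experiments."""
    return _load("plot_yields.csv", "plot_yields")


def load_reduction_levels() -> pd.DataFrame:
    """Published per-province reduction-level bands (D %, both phases)."""
    return _load("reduction_levels.csv", "reduction_levels")


def load_yield_changes() -> pd.DataFrame:
    """Present (2005-2016) vs future (2020-2050) seasonal yields and D%."""
    return _load("yield_changes.csv", "yield_changes")


def load_production() -> tuple[pd.DataFrame, pd.Series]:
    """(provincial production table, printed MRD totals row), 10^6 tons."""
    df = _load("production.csv", "production")
    mrd = df[df["province"] == "MRD"].iloc[0]
    return df[df["province"] != "MRD"].reset_index(drop=True), mrd


def load_future_calendar() -> EnsoCalendar:
    """High-probability future ENSO seasons, 2020-2050."""
    return EnsoCalendar.from_frame(_load("future_enso_calendar.csv", "enso_calendar"))


def load_historical_calendar() -> EnsoCalendar:
    """Approximate historical ENSO seasons 1976-2016 (replaceable config)."""
    return EnsoCalendar.from_frame(_load("historical_enso_calendar.csv", "enso_calendar"))


def load_scenario_deltas() -> pd.DataFrame:
    return _load("scenario_deltas.csv", "scenario_deltas")


def load_scenario_delta(name: str) -> ScenarioDelta:
    return ScenarioDelta.from_frame(load_scenario_deltas(), name)
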