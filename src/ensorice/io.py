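"""Schema-validated CSV input/output for all pipeline tables.

Every table the pipeline reads or writes is plain CSV with a documented
header.  A :class:`TableSchema` names the columns, their types, the key
columns that must be unique, columns that must be non-negative, and
columns whose values are restricted to a fixed set.  Violations raise
:class:`SchemaError` with row/column diagnostics.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TableSchema", "SchemaError", "read_table", "write_table", "round_half_up", "SCHEMAS"]


class SchemaError(ValueError):
    """A CSV does not conform to its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: Mapping[str, str]  # column -> dtype kind: 'str' | 'int' | 'float'
    key: Sequence[str] = ()
    non_negative: Sequence[str] = ()
    allowed: Mapping[str, Sequence[str]] = field(default_factory=dict)
    nullable: Sequence[str] = ()


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the printed tables' convention, not banker's)."""
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def validate_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    got = list(df.columns)
    want = list(schema.columns)
    if got != want:
        raise SchemaError(
            f"{schema.name}: header mismatch, expected {want}, got {got}"
        )
    out = df.copy()
    for col, kind in schema.columns.items():
        series = out[col]
        if kind in ("int", "float"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{schema.name}: non-numeric value {series[row]!r} in "
                    f"column {col!r}, row {row}"
                )
            if kind == "int":
                nonint = coerced.dropna() % 1 != 0
                if nonint.any():
                    row = int(nonint.idxmax())
                    raise SchemaError(
                        f"{schema.name}: non-integer value in column {col!r}, row {row}"
                    )
                out[col] = coerced.astype("Int64")
            else:
                out[col] = coerced.astype(float)
        else:
            out[col] = series.astype(str).where(series.notna(), None)
        if col not in schema.nullable:
            nulls = out[col].isna()
            if nulls.any():
                row = int(nulls.idxmax())
                raise SchemaError(
                    f"{schema.name}: missing value in required column {col!r}, row {row}"
                )
    for col in schema.non_negative:
        neg = out[col].astype(float) < 0
        if neg.any():
            row = int(neg.idxmax())
            raise SchemaError(
                f"{schema.name}: negative value {out[col][row]} in column "
                f"{col!r}, row {row}"
            )
    for col, values in schema.allowed.items():
        bad = ~out[col].isin(list(values)) & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{schema.name}: value {out[col][row]!r} in column {col!r}, "
                f"row {row} not in allowed set {list(values)}"
            )
    if schema.key:
        dup = out.duplicated(subset=list(schema.key))
        if dup.any():
            row = int(dup.idxmax())
            key = tuple(out.loc[row, list(schema.key)])
            raise SchemaError(
                f"{schema.name}: duplicate key {key} on columns {list(schema.key)}, row {row}"
            )
    return out


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    df = pd.read_csv(path)
    try:
        return validate_table(df, schema)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> None:
    if schema is not None:
        df = validate_table(df.reset_index(drop=True), schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


_SEASONS = ("WS", "SA", "AW")
_PHASES = ("ElNino", "LaNina")
_LEVELS = ("high", "medium", "low")

SCHEMAS: dict[str, TableSchema] = {
    "risk_areas": TableSchema(
        name="risk_areas",
        columns={
            "province": "str", "hazard": "str",
            "high": "float", "medium": "float", "low": "float", "none": "float",
        },
        key=("province", "hazard"),
        non_negative=("high", "medium", "low", "none"),
        allowed={"hazard": ("salinity", "flood")},
    ),
    "plot_yields": TableSchema(
        name="plot_yields",
        columns={"plot": "int", "season": "str", "ys": "float", "yo": "float"},
        key=("plot", "season"),
        non_negative=("ys", "yo"),
        allowed={"season": _SEASONS},
    ),
    "yield_panel": TableSchema(
        name="yield_panel",
        columns={
            "province": "str", "season": "str", "year": "int",
            "yo": "float", "ys": "float",
        },
        key=("province", "season", "year"),
        non_negative=("yo", "ys"),
        allowed={"season": _SEASONS},
        nullable=("yo", "ys"),
    ),
    "reduction_levels": TableSchema(
        name="reduction_levels",
        columns={
            "province": "str", "phase": "str", "level": "str",
            "d_lower": "float", "d_upper": "float", "d": "float",
        },
        key=("province", "phase", "level"),
        non_negative=("d_lower", "d_upper", "d"),
        allowed={"phase": _PHASES, "level": _LEVELS},
    ),
    "yield_changes": TableSchema(
        name="yield_changes",
        columns={
            "province": "str", "scenario": "str", "season": "str",
            "present": "float", "future": "float", "d_pct": "float",
        },
        key=("province", "scenario", "season"),
        non_negative=("present", "future"),
        allowed={"season": _SEASONS},
    ),
    "enso_calendar": TableSchema(
        name="enso_calendar",
        columns={"year": "int", "phase": "str", "season": "str"},
        key=("year", "season"),
        allowed={"phase": _PHASES, "season": ("WS", "AW")},
    ),
    "scenario_deltas": TableSchema(
        name="scenario_deltas",
        columns={"province": "str", "scenario": "str", "dt": "float", "drain_pct": "float"},
        key=("province", "scenario"),
        non_negative=("dt",),
    ),
    "areas": TableSchema(
        name="areas",
        columns={"province": "str", "season": "str", "area_ha": "float"},
        key=("province", "season"),
        non_negative=("area_ha",),
        allowed={"season": _SEASONS},
    ),
    "production": TableSchema(
        name="production",
        columns={
            "province": "str", "present": "float",
            "rcp45_no_enso": "float", "rcp85_no_enso": "float",
            "rcp45_elnino": "float", "rcp45_lanina": "float",
            "rcp85_elnino": "float", "rcp85_lanina": "float",
        },
        key=("province",),
        non_negative=(
            "present", "rcp45_no_enso", "rcp85_no_enso",
            "rcp45_elnino", "rcp45_lanina", "rcp85_elnino", "rcp85_lanina",
        ),
    ),
    "weather": TableSchema(
        name="weather",
        columns={
            "province": "str", "date": "str", "tmax": "float", "tmin": "float",
            "tmean": "float", "rainfall": "float", "sunshine": "float",
            "humidity": "float", "wind": "float", "evap": "float",
        },
        key=("province", "date"),
        non_negative=("rainfall", "sunshine", "humidity", "wind", "evap"),
    ),
}
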