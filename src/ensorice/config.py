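"""Configuration objects: ENSO anomaly magnitudes and RCP scenario deltas.

Defaults encode the observed delta-region contrasts: El Nino winters run
about +1 degC warmer with ~30 extra sunshine hours and ~25 mm/month extra
evaporation; La Nina winters bring ~80 mm/month extra rain.  The RCP4.5
scenario adds 1.4 degC to the annual mean by 2050 (RCP8.5: 1.8-1.9, default
midpoint 1.85) and scales rainfall by a per-province percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: Months of the ENSO anomaly window (December through April).
DEFAULT_ANOMALY_MONTHS: frozenset[int] = frozenset({12, 1, 2, 3, 4})


@dataclass(frozen=True)
class AnomalyConfig:
    """Magnitudes of the ENSO weather anomalies inside the Dec-Apr window."""

    elnino_dT: float = 1.0           # degC, added to tmin/tmean/tmax
    elnino_dSunshine: float = 30.0   # hours/month, added to sunshine
    elnino_dEvap: float = 25.0       # mm/month, added to evaporation
    lanina_dRain: float = 80.0       # mm/month, added to rainfall
    months: frozenset[int] = DEFAULT_ANOMALY_MONTHS

    def __post_init__(self) -> None:
        for name in ("elnino_dT", "elnino_dSunshine", "elnino_dEvap", "lanina_dRain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        bad = set(self.months) - set(range(1, 13))
        if bad:
            raise ValueError(f"anomaly months out of range: {sorted(bad)}")


class UnknownProvinceError(KeyError):
    """A province is missing from a per-province configuration table."""


@dataclass(frozen=True)
class ScenarioDelta:
    """An RCP scenario as exogenous climate deltas.

    ``dT`` is added uniformly to all temperatures; ``drain_pct`` scales
    daily rainfall multiplicatively per province (Drain is stated in %).
    """

    name: str
    dT: float
    drain_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dT < 0:
            raise ValueError("dT must be >= 0")

    def rain_factor(self, province: str) -> float:
        try:
            return 1.0 + float(self.drain_pct[province]) / 100.0
        except KeyError:
            raise UnknownProvinceError(
                f"province {province!r} missing from scenario {self.name!r} "
                "rainfall-delta table"
            ) from None

    @classmethod
    def null(cls) -> "ScenarioDelta":
        """The no-change (baseline) scenario."""
        return cls(name="baseline", dT=0.0, drain_pct=_ZeroRain())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str) -> "ScenarioDelta":
        rows = df[df["scenario"] == name]
        if rows.empty:
            raise ValueError(f"scenario {name!r} not present in delta table")
        dts = rows["dt"].unique()
        if len(dts) != 1:
            raise ValueError(f"scenario {name!r} has inconsistent dT values: {dts}")
        return cls(
            name=name,
            dT=float(dts[0]),
            drain_pct=dict(zip(rows["province"], rows["drain_pct"].astype(float))),
        )


class _ZeroRain(dict):
    """Rainfall-delta mapping that is zero for every province."""

    def __missing__(self, key: str) -> float:
        return 0.0
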