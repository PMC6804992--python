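"""ENSO calendars: which years carry El Nino / La Nina conditions.

An :class:`EnsoCalendar` is a validated set of (year, phase, season)
entries.  El Nino entries pair only with the winter-spring (WS) season
and La Nina entries only with the autumn-winter (AW) season, mirroring
the salinity-intrusion / flooding hazard mapping of the delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .seasons import HAZARD_SEASON, Phase, Season


class CalendarError(ValueError):
    """Raised for phase/season pairings the hazard mapping forbids."""


@dataclass(frozen=True)
class EnsoCalendar:
    """Set of ENSO-affected cropping seasons keyed by harvest year."""

    entries: tuple[tuple[int, Phase, Season], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[tuple[int, Season]] = set()
        for year, phase, season in self.entries:
            if phase is Phase.NEUTRAL:
                raise CalendarError("neutral years are implicit; do not list them")
            if HAZARD_SEASON[phase] is not season:
                raise CalendarError(
                    f"{phase.value} may only affect the "
                    f"{HAZARD_SEASON[phase].value} season, got {season.value} ({year})"
                )
            if (year, season) in seen:
                raise CalendarError(f"duplicate calendar entry for {year} {season.value}")
            seen.add((year, season))

    @classmethod
    def from_records(cls, records: Iterable[tuple[int, str, str]]) -> "EnsoCalendar":
        return cls(tuple((int(y), Phase(p), Season(s)) for y, p, s in records))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnsoCalendar":
        return cls.from_records(df[["year", "phase", "season"]].itertuples(index=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(y, p.value, s.value) for y, p, s in self.entries],
            columns=["year", "phase", "season"],
        )

    def phase_of(self, year: int, season: Season | str) -> Phase:
        season = Season(season)
        for y, phase, s in self.entries:
            if y == year and s is season:
                return phase
        return Phase.NEUTRAL

    def phase_of_year(self, year: int) -> Phase:
        """Dominant phase of a calendar year (first listed entry wins)."""
        for y, phase, _ in self.entries:
            if y == year:
                return phase
        return Phase.NEUTRAL

    def years(self, phase: Phase) -> tuple[int, ...]:
        return tuple(sorted(y for y, p, _ in self.entries if p is phase))

    def __iter__(self) -> Iterator[tuple[int, Phase, Season]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)
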