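"""Cropping seasons, ENSO phases and the Mekong River Delta province set.

The Mekong River Delta (MRD) grows rice in up to three seasons per year:
winter-spring (WS, sown ~November, harvested ~February), summer-autumn
(SA, April-July) and autumn-winter (AW, August-November).  Salinity
intrusion in El Nino years threatens the WS crop; flooding in La Nina
years threatens the AW crop; the SA crop faces neither hazard.
"""

from __future__ import annotations

import enum
from datetime import date


class Season(str, enum.Enum):
    WS = "WS"
    SA = "SA"
    AW = "AW"


class Phase(str, enum.Enum):
    EL_NINO = "ElNino"
    LA_NINA = "LaNina"
    NEUTRAL = "Neutral"


class Hazard(str, enum.Enum):
    """Climate hazards as mapped in the provincial risk maps."""

    SALINITY = "salinity"  # El Nino / WS
    FLOOD = "flood"        # La Nina / AW


#: Hazard season affected by each non-neutral ENSO phase.
HAZARD_SEASON: dict[Phase, Season] = {
    Phase.EL_NINO: Season.WS,
    Phase.LA_NINA: Season.AW,
}

PHASE_HAZARD: dict[Phase, Hazard] = {
    Phase.EL_NINO: Hazard.SALINITY,
    Phase.LA_NINA: Hazard.FLOOD,
}

#: The 13 MRD provinces, in the customary (risk-map table) order.
MRD_PROVINCES: tuple[str, ...] = (
    "Long An",
    "Tien Giang",
    "Ben Tre",
    "Tra Vinh",
    "Vinh Long",
    "Dong Thap",
    "An Giang",
    "Kien Giang",
    "Can Tho",
    "Hau Giang",
    "Soc Trang",
    "Bac Lieu",
    "Ca Mau",
)

#: Seasons actually cropped per province.  Ca Mau has no winter-spring crop.
SEASONS_BY_PROVINCE: dict[str, tuple[Season, ...]] = {
    p: ((Season.SA, Season.AW) if p == "Ca Mau" else (Season.WS, Season.SA, Season.AW))
    for p in MRD_PROVINCES
}


def season_window(season: Season | str, year: int) -> tuple[date, date]:
    """Calendar window of a cropping season labelled by its harvest year.

    WS spans Nov 1 of ``year - 1`` through Feb 28 of ``year``; SA spans
    Apr 1 - Jul 31 and AW Aug 1 - Nov 30 of ``year``.
    """
    season = Season(season)
    if season is Season.WS:
        return date(year - 1, 11, 1), date(year, 2, 28)
    if season is Season.SA:
        return date(year, 4, 1), date(year, 7, 31)
    return date(year, 8, 1), date(year, 11, 30)
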