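"""Model-evaluation statistics: Nash-Sutcliffe efficiency, RMSE, R^2.

The Nash-Sutcliffe model efficiency

    Ef = 1 - sum((YO_i - YS_i)^2) / sum((YO_i - mean(YO))^2)

equals 1 for a perfect match, 0 when the model performs no better than
predicting the observed mean, and goes negative when it does worse.
R^2 is the squared Pearson correlation of observed and simulated series,
which is what the printed plot-level validation statistics correspond to
(not regression through the origin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["model_efficiency", "rmse", "r_squared", "seasonal_stats", "validation_report"]


class ConstantSeriesError(ValueError):
    """The statistic is undefined for a constant series."""


def _pair(yo, ys) -> tuple[np.ndarray, np.ndarray]:
    yo = np.asarray(yo, dtype=float).ravel()
    ys = np.asarray(ys, dtype=float).ravel()
    if yo.shape != ys.shape:
        raise ValueError(f"length mismatch: {yo.size} observed vs {ys.size} simulated")
    if np.isnan(yo).any() or np.isnan(ys).any():
        raise ValueError("paired series contain NaN")
    return yo, ys


def model_efficiency(yo, ys) -> float:
    """Nash-Sutcliffe efficiency in (-inf, 1]."""
    yo, ys = _pair(yo, ys)
    if yo.size < 2:
        raise ValueError("model efficiency needs at least 2 pairs")
    denom = float(np.sum((yo - yo.mean()) ** 2))
    if denom == 0.0:
        raise ConstantSeriesError("observed series is constant; Ef undefined")
    return 1.0 - float(np.sum((yo - ys) ** 2)) / denom


def rmse(yo, ys) -> float:
    """Root mean square error, ton/ha."""
    yo, ys = _pair(yo, ys)
    if yo.size == 0:
        raise ValueError("rmse of an empty series")
    return float(np.sqrt(np.mean((yo - ys) ** 2)))


def r_squared(yo, ys) -> float:
    """Squared Pearson correlation in [0, 1]."""
    yo, ys = _pair(yo, ys)
    if yo.size < 2:
        raise ValueError("r_squared needs at least 2 pairs")
    if np.ptp(yo) == 0 or np.ptp(ys) == 0:
        raise ConstantSeriesError("r_squared undefined for a constant series")
    return float(stats.pearsonr(yo, ys)[0] ** 2)


def seasonal_stats(plot_df: pd.DataFrame) -> pd.DataFrame:
    """Per-season RMSE and R^2 from a plot table with yo/ys columns."""
    rows = []
    for season, grp in plot_df.groupby("season", sort=False):
        rows.append(
            {
                "season": season,
                "n": len(grp),
                "rmse": rmse(grp["yo"], grp["ys"]),
                "r_squared": r_squared(grp["yo"], grp["ys"]),
            }
        )
    return pd.DataFrame(rows)


def validation_report(panel: pd.DataFrame, min_years: int = 5) -> pd.DataFrame:
    """Per province x season Nash-Sutcliffe efficiency with availability flags.

    Cells with fewer than ``min_years`` complete (YO, YS) years, or with
    a constant observed series, are marked unavailable rather than
    raising — mirroring how sparse provincial records are reported.
    """
    rows = []
    for (province, season), grp in panel.groupby(["province", "season"], sort=False):
        ok = grp[["yo", "ys"]].notna().all(axis=1)
        n = int(ok.sum())
        ef = np.nan
        available = n >= min_years
        if available:
            try:
                ef = model_efficiency(grp.loc[ok, "yo"], grp.loc[ok, "ys"])
            except ConstantSeriesError:
                available = False
        rows.append(
            {
                "province": province,
                "season": season,
                "n_years": n,
                "ef": ef if available else np.nan,
                "available": available,
            }
        )
    return pd.DataFrame(rows)
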