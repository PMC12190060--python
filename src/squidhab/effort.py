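"""Normalized fishing effort (CPUE) from vessel-count fields.

The relative-abundance proxy is the vessel count per cell divided by the
maximum cell count of the same period at the same resolution, so every
period's effort field lies in [0, 1] with its busiest cell at exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterField, season_of_month

__all__ = ["CPUEField", "cpue", "activity_summary"]


@dataclass
class CPUEField:
    """Normalized vessel effort in [0, 1] for one period on one grid."""

    grid: GridSpec
    period: str
    values: np.ndarray
    boat_max: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.boat_max <= 0:
            raise ValueError("boat_max must be a positive integer")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def cpue(counts: RasterField) -> CPUEField:
    """Normalize a vessel-count field by its own maximum cell count.

    Rejects all-zero periods — with no effort anywhere the ratio is undefined
    and the period carries no habitat signal.
    """
    vals = counts.values
    finite = vals[~np.isnan(vals)]
    if finite.size == 0 or np.nanmax(vals) <= 0:
        raise ValueError(f"period {counts.period!r}: all counts are zero, CPUE undefined")
    if np.any(finite < 0) or np.any(finite != np.round(finite)):
        raise ValueError("counts must be non-negative integers")
    boat_max = int(np.nanmax(vals))
    return CPUEField(counts.grid, counts.period, vals / boat_max, boat_max)


def activity_summary(records: pd.DataFrame, count_mode: str = "distinct") -> pd.DataFrame:
    """Per-month and per-season distinct vessel totals with monthly shares.

    Returns one row per calendar month with columns ``month``, ``season``,
    ``vessels`` (distinct vessel ids active that month, or vessel-day tallies
    in ``vessel_days`` mode), ``season_vessels`` (same measure pooled over
    the season) and ``share_pct`` — the month's percentage of its season
    total, rounded to 2 decimals. In distinct-id mode a vessel active in two
    months of one season is counted once in the season total, so monthly
    shares may sum to more than 100%.
    """
    ts = pd.to_datetime(records["datetime"], errors="coerce", format="mixed")
    ok = ts.notna()
    df = pd.DataFrame(
        {"vessel_id": records.loc[ok, "vessel_id"], "month": ts[ok].dt.month}
    )
    df["season"] = df["month"].map(season_of_month)
    if count_mode == "vessel_days":
        df["key"] = records.loc[ok, "vessel_id"].astype(str) + "@" + ts[ok].dt.date.astype(str)
    elif count_mode == "distinct":
        df["key"] = df["vessel_id"]
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")

    monthly = df.groupby("month")["key"].nunique()
    seasonal = df.groupby("season")["key"].nunique()
    rows = []
    for m in sorted(monthly.index):
        season = season_of_month(m)
        tot = int(seasonal[season])
        n = int(monthly[m])
        rows.append(
            {
                "month": m,
                "season": season,
                "vessels": n,
                "season_vessels": tot,
                "share_pct": round(100.0 * n / tot, 2) if tot else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("month").reset_index(drop=True)
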