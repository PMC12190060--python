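"""Spatial and temporal alignment of fishery and environmental data.

Covers block-mean aggregation between nested grids, per-period vessel
counting, composition of daily fields into period means, and kriging
gap-fill (re-exported from :mod:`squidhab.kriging`).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterField, TemporalScale
from .kriging import fill_missing  # noqa: F401  (public re-export)

__all__ = ["aggregate_field", "aggregate_vessels", "temporal_compose", "fill_missing"]

log = logging.getLogger(__name__)

VESSEL_COLUMNS = ("vessel_id", "datetime", "lon", "lat")


def aggregate_field(fine: RasterField, target: GridSpec) -> RasterField:
    """Block-average a fine field onto a coarser, nested grid.

    Each coarse cell is the mean of the non-missing fine cells it contains;
    it is missing only when every contained fine cell is missing.
    """
    if not target.is_nested_in(fine.grid):
        ratio = target.cell_size / fine.grid.cell_size
        raise ValueError(
            f"target grid is not nested in the source grid "
            f"(cell-size ratio {ratio:.6g} must be a whole number and the "
            f"bounds must coincide)"
        )
    f = round(target.cell_size / fine.grid.cell_size)
    vals = fine.values.reshape(target.n_lat, f, target.n_lon, f)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(vals, axis=(1, 3))
    return RasterField(target, fine.period, fine.variable, fine.units, coarse)


def _assign_periods(records: pd.DataFrame, temporal: TemporalScale) -> pd.Series:
    ts = pd.to_datetime(records["datetime"], errors="coerce", format="mixed")
    bad = ts.isna()
    if bad.any():
        log.warning("dropped %d records with malformed timestamps", int(bad.sum()))
    months = ts.dt.month
    periods = pd.Series(index=records.index, dtype=object)
    ok = ~bad
    periods[ok] = [temporal.period_of(int(m)) for m in months[ok]]
    return periods


def aggregate_vessels(
    records: pd.DataFrame,
    grid: GridSpec,
    temporal: TemporalScale,
    count_mode: str = "distinct",
) -> dict[str, RasterField]:
    """Count vessels per grid cell per period.

    ``count_mode="distinct"`` counts distinct vessel ids per cell-period (the
    default effort measure); ``"vessel_days"`` counts distinct (vessel, day)
    pairs, so a vessel working the same cell on several days contributes once
    per day. Records outside the grid, with malformed timestamps, or in months
    excluded by the temporal scale are dropped (counts logged).

    Returns one integer count field per period that has any record.
    """
    if count_mode not in ("distinct", "vessel_days"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    missing_cols = [c for c in VESSEL_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"vessel records missing columns: {missing_cols}")

    periods = _assign_periods(records, temporal)
    rows, cols, inside = grid.locate(records["lon"].to_numpy(), records["lat"].to_numpy())
    keep = inside & periods.notna().to_numpy()
    n_drop = len(records) - int(keep.sum())
    if n_drop:
        log.info("aggregate_vessels: dropped %d of %d records", n_drop, len(records))

    df = pd.DataFrame(
        {
            "vessel_id": records["vessel_id"].to_numpy()[keep],
            "period": periods.to_numpy()[keep],
            "row": rows[keep],
            "col": cols[keep],
        }
    )
    if count_mode == "vessel_days":
        days = pd.to_datetime(records["datetime"], errors="coerce", format="mixed")
        df["day"] = days.dt.floor("D").to_numpy()[keep]
        key_cols = ["vessel_id", "day"]
    else:
        key_cols = ["vessel_id"]

    out: dict[str, RasterField] = {}
    for period, sub in df.groupby("period", sort=True):
        uniq = sub.drop_duplicates(subset=key_cols + ["row", "col"])
        counts = np.zeros(grid.shape, dtype=float)
        np.add.at(counts, (uniq["row"].to_numpy(), uniq["col"].to_numpy()), 1.0)
        out[str(period)] = RasterField(grid, str(period), "vessel_count", "vessels", counts)
    return out


def temporal_compose(
    daily: list[tuple[pd.Timestamp, RasterField]] | dict,
    temporal: TemporalScale,
) -> dict[str, RasterField]:
    """Average daily fields into period means (day-weighted).

    ``daily`` maps dates to fields on one shared grid. The period mean is the
    per-cell mean over all days in the period, ignoring missing days; a cell
    is missing in the output only if it is missing on every day.
    """
    items = list(daily.items()) if isinstance(daily, dict) else list(daily)
    if not items:
        raise ValueError("no daily fields supplied")
    grid = items[0][1].grid
    variable, units = items[0][1].variable, items[0][1].units
    for _, fld in items:
        if fld.grid != grid:
            raise ValueError("daily fields must share one grid")

    by_period: dict[str, list[np.ndarray]] = defaultdict(list)
    for date, fld in items:
        period = temporal.period_of(pd.Timestamp(date).month)
        if period is not None:
            by_period[period].append(fld.values)

    if not by_period:
        raise ValueError("no daily fields fall inside any period of the temporal scale")

    out = {}
    for period, stacks in by_period.items():
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.stack(stacks), axis=0)
        out[period] = RasterField(grid, period, variable, units, mean)
    return out
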