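"""Readers and writers: NetCDF and long-CSV raster fields, vessel CSVs,
and result tables.

NetCDF layout is CF-style ``(time, lat, lon)`` with coordinate centres in
decimal degrees and a units attribute per variable. The long-CSV dialect has
columns ``period, lat, lon, value`` (cell centres). Writers are deterministic
given their inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, RasterField

__all__ = [
    "fields_to_dataset",
    "dataset_to_fields",
    "write_env",
    "read_env",
    "write_env_csv",
    "read_env_csv",
    "read_vessels",
    "write_vessels",
    "write_table",
]

VESSEL_SCHEMA = ("vessel_id", "datetime", "lon", "lat")


def _grid_from_centers(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    dlat = float(np.diff(lats).mean()) if len(lats) > 1 else 0.1
    dlon = float(np.diff(lons).mean()) if len(lons) > 1 else dlat
    if not np.isclose(dlat, dlon, rtol=1e-6):
        raise ValueError(f"anisotropic cells not supported (dlat={dlat}, dlon={dlon})")
    # snap to 6 decimals so float noise from stored coordinates cannot break
    # grid-equality checks downstream
    size = round(dlat, 6)
    return GridSpec(
        lon_min=round(float(lons[0]) - size / 2, 6),
        lon_max=round(float(lons[-1]) + size / 2, 6),
        lat_min=round(float(lats[0]) - size / 2, 6),
        lat_max=round(float(lats[-1]) + size / 2, 6),
        cell_size=size,
    )


def fields_to_dataset(fields: dict[str, dict[str, RasterField]]) -> xr.Dataset:
    """Stack {period: {variable: field}} into one (time, lat, lon) dataset."""
    periods = sorted(fields)
    variables = sorted({v for per in fields.values() for v in per})
    grid = fields[periods[0]][variables[0]].grid
    data = {}
    for var in variables:
        stack = np.stack([fields[p][var].values for p in periods])
        units = fields[periods[0]][var].units
        data[var] = xr.DataArray(
            stack,
            dims=("time", "lat", "lon"),
            coords={
                "time": periods,
                "lat": grid.lat_centers,
                "lon": grid.lon_centers,
            },
            attrs={"units": units},
        )
    ds = xr.Dataset(data)
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    ds.attrs["cell_size"] = grid.cell_size
    return ds


def dataset_to_fields(ds: xr.Dataset) -> dict[str, dict[str, RasterField]]:
    """Inverse of :func:`fields_to_dataset`."""
    grid = _grid_from_centers(ds["lat"].values, ds["lon"].values)
    out: dict[str, dict[str, RasterField]] = {}
    periods = [str(p) for p in ds["time"].values]
    for i, period in enumerate(periods):
        out[period] = {}
        for var in ds.data_vars:
            da = ds[var]
            out[period][str(var)] = RasterField(
                grid,
                period,
                str(var),
                str(da.attrs.get("units", "")),
                np.asarray(da.values[i], dtype=float),
            )
    return out


def write_env(fields: dict[str, dict[str, RasterField]], path: str | Path) -> None:
    """Write period fields to NetCDF (NETCDF3 via the scipy backend)."""
    ds = fields_to_dataset(fields)
    # encode period labels as fixed-width strings for netCDF3 compatibility
    ds = ds.assign_coords(time=np.array(ds["time"].values, dtype="S16"))
    ds.to_netcdf(Path(path), engine="scipy")


def read_env(path: str | Path) -> dict[str, dict[str, RasterField]]:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds = ds.load()
    times = [
        t.decode() if isinstance(t, (bytes, np.bytes_)) else str(t)
        for t in ds["time"].values
    ]
    ds = ds.assign_coords(time=times)
    return dataset_to_fields(ds)


def write_env_csv(fields: dict[str, dict[str, RasterField]], path: str | Path) -> None:
    """Long-format CSV: period, variable, lat, lon, value (cell centres)."""
    rows = []
    for period in sorted(fields):
        for var in sorted(fields[period]):
            fld = fields[period][var]
            lon_c, lat_c = np.meshgrid(fld.grid.lon_centers, fld.grid.lat_centers)
            rows.append(
                pd.DataFrame(
                    {
                        "period": period,
                        "variable": var,
                        "lat": lat_c.ravel(),
                        "lon": lon_c.ravel(),
                        "value": fld.values.ravel(),
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False)


def read_env_csv(path: str | Path, units: dict[str, str] | None = None) -> dict[str, dict[str, RasterField]]:
    df = pd.read_csv(Path(path))
    required = {"period", "variable", "lat", "lon", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment CSV missing columns: {sorted(missing)}")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    grid = _grid_from_centers(lats, lons)
    lat_idx = {v: i for i, v in enumerate(lats)}
    lon_idx = {v: i for i, v in enumerate(lons)}
    out: dict[str, dict[str, RasterField]] = {}
    for (period, var), sub in df.groupby(["period", "variable"]):
        vals = np.full(grid.shape, np.nan)
        r = sub["lat"].map(lat_idx).to_numpy()
        c = sub["lon"].map(lon_idx).to_numpy()
        vals[r, c] = sub["value"].to_numpy()
        out.setdefault(str(period), {})[str(var)] = RasterField(
            grid, str(period), str(var), (units or {}).get(str(var), ""), vals
        )
    return out


def read_vessels(path: str | Path) -> pd.DataFrame:
    """Read and validate a vessel-record CSV (vessel_id, datetime, lon, lat)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in VESSEL_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"vessel CSV {path}: missing columns {missing}")
    for col in ("lon", "lat"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"vessel CSV {path}: non-numeric {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_vessels(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, list(VESSEL_SCHEMA)].to_csv(Path(path), index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)
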