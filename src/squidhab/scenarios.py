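"""SST-shift scenario analysis: habitat-area accounting under uniform
temperature perturbations.

The seasonal baseline SST field is shifted by a set of additive deltas
(default 0, +/-0.2, +/-0.5, +/-1.0 degC), HSI is predicted from the seasonal
single-factor SST model, and habitat areas are accounted on the sphere:

* "suitable" band: 0.5 < HSI <= 0.75,
* "optimal": HSI > 0.75,
* "suitable_or_better": HSI > 0.5 (the union of the two).

Each (season, delta, class) row reports the area in km^2, the ratio to the
analysed region's total area (%), and the change versus the season's
baseline (%). When the baseline area is zero the change column reports the
scenario's area ratio instead — a nonstandard but deliberate convention, so
a habitat appearing from nothing is described by how much of the region it
now covers rather than by an undefined percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterField
from .hsi import HSIField
from .suitability import GaussianSIFit, si_predict

__all__ = [
    "EARTH_RADIUS_KM",
    "ScenarioSpec",
    "HABITAT_CLASSES",
    "shift_sst",
    "cell_area",
    "cell_areas",
    "region_area",
    "habitat_area",
    "area_change_pct",
    "scenario_suite",
]

EARTH_RADIUS_KM = 6371.0088

DEFAULT_DELTAS = (0.0, 0.2, 0.5, 1.0, -0.2, -0.5, -1.0)

HABITAT_CLASSES = ("suitable", "optimal", "suitable_or_better")


@dataclass(frozen=True)
class ScenarioSpec:
    """SST deltas to apply plus the per-season HSI model."""

    deltas: tuple[float, ...] = DEFAULT_DELTAS
    models: dict[str, GaussianSIFit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(math.isfinite(d) for d in self.deltas):
            raise ValueError("deltas must be finite")
        if 0.0 not in self.deltas:
            object.__setattr__(self, "deltas", (0.0,) + tuple(self.deltas))


def shift_sst(fld: RasterField, delta: float) -> RasterField:
    """Uniform additive SST perturbation; the period label records the scenario."""
    out = fld.copy()
    out.values = fld.values + delta
    if delta != 0.0:
        out.period = f"{fld.period}{delta:+g}degC"
    return out


def cell_area(grid: GridSpec, row: int) -> float:
    """Spherical area (km^2) of one cell in the given latitude row:
    R^2 * dlam * (sin(lat_top) - sin(lat_bottom)). All cells in a row have
    equal area; area shrinks toward the poles."""
    lat0 = math.radians(grid.lat_min + row * grid.cell_size)
    lat1 = math.radians(grid.lat_min + (row + 1) * grid.cell_size)
    dlam = math.radians(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(lat1) - math.sin(lat0))


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell spherical areas (km^2), shape = grid.shape."""
    lat_edges = np.radians(grid.lat_edges)
    band = EARTH_RADIUS_KM**2 * math.radians(grid.cell_size) * np.diff(np.sin(lat_edges))
    return np.repeat(band[:, None], grid.n_lon, axis=1)


def region_area(grid: GridSpec, mask: np.ndarray | None = None) -> float:
    """Total area of the analysed cells (all cells unless a mask is given)."""
    a = cell_areas(grid)
    if mask is not None:
        a = a[mask]
    return float(a.sum())


def _class_mask(values: np.ndarray, habitat_class: str) -> np.ndarray:
    if habitat_class == "suitable":
        return (values > 0.5) & (values <= 0.75)
    if habitat_class == "optimal":
        return values > 0.75
    if habitat_class == "suitable_or_better":
        return values > 0.5
    raise ValueError(f"unknown habitat class {habitat_class!r}")


def habitat_area(hsi: HSIField, habitat_class: str = "suitable") -> float:
    """Summed spherical area (km^2) of the cells in one habitat class."""
    mask = _class_mask(np.nan_to_num(hsi.values, nan=-1.0), habitat_class)
    return float(cell_areas(hsi.grid)[mask].sum())


def area_change_pct(area: float, baseline: float, area_ratio: float) -> float:
    """Change versus baseline in percent, under the baseline-zero convention:
    when the baseline area is zero the scenario's area ratio is reported
    instead of an undefined percentage."""
    if baseline > 0:
        return 100.0 * (area - baseline) / baseline
    return area_ratio


def scenario_suite(
    spec: ScenarioSpec,
    baseline_sst: dict[str, RasterField],
) -> pd.DataFrame:
    """Run every (season, delta) scenario and account habitat areas.

    ``baseline_sst`` maps season name -> baseline SST field; each season needs
    a fitted model in ``spec.models`` (seasons without one are skipped with a
    warning row omitted). Returns a tidy table with columns season, delta_degC,
    habitat_class, area_km2, area_ratio_pct, area_change_pct.
    """
    rows: list[dict] = []
    for season, sst in baseline_sst.items():
        model = spec.models.get(season)
        if model is None:
            import warnings

            warnings.warn(f"no HSI model for season {season!r}; skipped", stacklevel=2)
            continue
        total = region_area(sst.grid, ~np.isnan(sst.values))

        def predict(delta: float) -> HSIField:
            shifted = shift_sst(sst, delta)
            pred = si_predict(model, shifted.values)
            pred = np.where(np.isnan(shifted.values), np.nan, pred)
            return HSIField(sst.grid, shifted.period, pred)

        base_hsi = predict(0.0)
        base_areas = {cls: habitat_area(base_hsi, cls) for cls in HABITAT_CLASSES}
        for delta in spec.deltas:
            hsi = predict(delta)
            for cls in HABITAT_CLASSES:
                area = habitat_area(hsi, cls)
                ratio = 100.0 * area / total if total > 0 else float("nan")
                if delta == 0.0:
                    change = float("nan")  # baseline row has no change column
                else:
                    change = area_change_pct(area, base_areas[cls], ratio)
                rows.append(
                    {
                        "season": season,
                        "delta_degC": delta,
                        "habitat_class": cls,
                        "area_km2": area,
                        "area_ratio_pct": round(ratio, 2),
                        "area_change_pct": round(change, 2) if math.isfinite(change) else change,
                    }
                )
    return pd.DataFrame(rows)
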