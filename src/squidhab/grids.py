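"""Grid bookkeeping: spatial grids, temporal scales, raster fields, and the
six (spatial x temporal) modelling schemes.

All grids are plate-carree lat/lon boxes. Cells are half-open ``[lo, hi)`` in
both axes and labelled by their lower-left corner; a point on a shared edge
therefore belongs to exactly one cell. Longitudes are east-positive decimal
degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "TemporalScale",
    "RasterField",
    "Scheme",
    "SCHEMES",
    "SEASON_MONTHS",
    "REPRESENTATIVE_MONTHS",
]

#: meteorological season -> calendar months (winter spans the year boundary:
#: December of year y belongs with January-February of year y+1).
SEASON_MONTHS: Mapping[str, tuple[int, int, int]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}

#: one representative month per season (March, June, September, December).
REPRESENTATIVE_MONTHS: Mapping[str, int] = {
    "spring": 3,
    "summer": 6,
    "autumn": 9,
    "winter": 12,
}

SEASON_ORDER = ("spring", "summer", "autumn", "winter")

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


def _n_cells(lo: float, hi: float, size: float) -> int:
    n = (hi - lo) / size
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
        raise ValueError(
            f"cell_size {size} does not divide extent [{lo}, {hi}] "
            f"(remainder {(hi - lo) - n_round * size:+.6g})"
        )
    return n_round


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with half-open cells labelled by lower-left corner."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.lon_max <= self.lon_min:
            raise ValueError("lon_max must exceed lon_min")
        if self.lat_max <= self.lat_min:
            raise ValueError("lat_max must exceed lat_min")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        _n_cells(self.lon_min, self.lon_max, self.cell_size)
        _n_cells(self.lat_min, self.lat_max, self.cell_size)

    @property
    def n_lon(self) -> int:
        return _n_cells(self.lon_min, self.lon_max, self.cell_size)

    @property
    def n_lat(self) -> int:
        return _n_cells(self.lat_min, self.lat_max, self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — row index is latitude, ascending from lat_min."""
        return (self.n_lat, self.n_lon)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.cell_size * np.arange(self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.cell_size * np.arange(self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (np.arange(self.n_lat) + 0.5)

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) cell indices under the lower-left half-open rule.

        Returns ``(rows, cols, inside)`` where ``inside`` marks points within
        the grid bounds; rows/cols are only valid where ``inside`` is True.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # tiny relative epsilon so points lying exactly on a cell edge are not
        # pushed into the lower cell by floating-point division error
        eps = 1e-9
        cols = np.floor((lon - self.lon_min) / self.cell_size + eps).astype(int)
        rows = np.floor((lat - self.lat_min) / self.cell_size + eps).astype(int)
        inside = (
            (cols >= 0) & (cols < self.n_lon) & (rows >= 0) & (rows < self.n_lat)
        )
        return rows, cols, inside

    def is_nested_in(self, fine: "GridSpec") -> bool:
        """True if this (coarser) grid shares origin/extent with ``fine`` and its
        cell size is an integer multiple of the fine cell size."""
        ratio = self.cell_size / fine.cell_size
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            return False
        same = all(
            math.isclose(a, b, abs_tol=1e-9)
            for a, b in (
                (self.lon_min, fine.lon_min),
                (self.lon_max, fine.lon_max),
                (self.lat_min, fine.lat_min),
                (self.lat_max, fine.lat_max),
            )
        )
        return same

    def with_cell_size(self, cell_size: float) -> "GridSpec":
        return replace(self, cell_size=cell_size)


@dataclass(frozen=True)
class TemporalScale:
    """Temporal aggregation scale: calendar months or meteorological seasons.

    ``kind`` is ``"month"`` or ``"season"``. In season mode the default maps
    each season to its three meteorological months; ``representative`` mode
    instead keeps only March/June/September/December, one per season.
    """

    kind: str = "season"
    representative: bool = False
    season_months: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(SEASON_MONTHS)
    )

    def __post_init__(self) -> None:
        if self.kind not in ("month", "season"):
            raise ValueError(f"kind must be 'month' or 'season', got {self.kind!r}")
        if self.kind == "season" and not self.representative:
            months = sorted(m for ms in self.season_months.values() for m in ms)
            if months != list(range(1, 13)):
                raise ValueError("season mapping must cover all 12 months exactly once")

    def period_of(self, month: int) -> str | None:
        """Period label for a calendar month (1-12), or None if the month is
        excluded (representative season mode keeps 4 months only)."""
        if not 1 <= month <= 12:
            raise ValueError(f"month out of range: {month}")
        if self.kind == "month":
            return f"{month:02d}"
        if self.representative:
            for season, rep in REPRESENTATIVE_MONTHS.items():
                if month == rep:
                    return season
            return None
        for season, months in self.season_months.items():
            if month in months:
                return season
        return None

    @property
    def periods(self) -> tuple[str, ...]:
        if self.kind == "month":
            return tuple(f"{m:02d}" for m in range(1, 13))
        return SEASON_ORDER


@dataclass
class RasterField:
    """Gridded values of one variable for one period on one GridSpec.

    ``values`` has shape ``grid.shape`` = (n_lat, n_lon) with NaN marking
    missing cells.
    """

    grid: GridSpec
    period: str
    variable: str
    units: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "RasterField":
        return RasterField(
            self.grid, self.period, self.variable, self.units, self.values.copy()
        )


@dataclass(frozen=True)
class Scheme:
    """One (spatial resolution, temporal scale) modelling scheme."""

    scheme_id: int
    cell_size: float
    temporal_kind: str

    @property
    def temporal(self) -> TemporalScale:
        return TemporalScale(kind=self.temporal_kind)

    def label(self) -> str:
        return f"{self.cell_size}deg-{self.temporal_kind}"


#: the six standard schemes: {0.1, 0.5, 1.0} degrees x {season, month}.
SCHEMES: tuple[Scheme, ...] = (
    Scheme(1, 0.1, "season"),
    Scheme(2, 0.1, "month"),
    Scheme(3, 0.5, "season"),
    Scheme(4, 0.5, "month"),
    Scheme(5, 1.0, "season"),
    Scheme(6, 1.0, "month"),
)


def season_of_month(month: int) -> str:
    """Meteorological season of a calendar month (winter = Dec-Feb)."""
    return _MONTH_TO_SEASON[month]
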