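"""Synthetic fishery and environment generator.

Emulates the statistical structure the habitat analysis assumes, so the whole
pipeline is testable without any proprietary vessel-monitoring or satellite
download:

* tropical SST fields (sinusoidal annual cycle + latitudinal gradient +
  smooth noise, clipped to a configured physical range),
* SST anomaly as a smooth zero-mean field plus a configurable offset,
* lognormal chlorophyll-a,
* vessel placement as an inhomogeneous Poisson process over cells whose
  intensity is a product of Gaussian responses to the three fields — the same
  unimodal response family the downstream suitability fits assume, so truth
  parameters are recoverable end to end.

All randomness flows from one integer seed through spawned child generators;
no global state is touched.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, RasterField

__all__ = [
    "FieldConfig",
    "TruthParams",
    "DEFAULT_REGION",
    "generate_env_fields",
    "generate_vessel_records",
    "generate_survey_field",
    "inject_missing",
]

#: default study region: 109-117 E, 6-12 N at 0.1 degrees — a tropical
#: offshore box whose extent nests the 0.1/0.5/1 degree scheme grids.
DEFAULT_REGION = GridSpec(109.0, 117.0, 6.0, 12.0, 0.1)


@dataclass(frozen=True)
class FieldConfig:
    """Statistical configuration of the generated environmental fields.

    SST (degC) = annual mean + seasonal cosine (peak at ``sst_peak_month``)
    + linear latitudinal gradient + smoothed Gaussian noise, clipped to
    ``sst_clip``. SSTA (degC) is smoothed noise around ``ssta_offset``.
    CHL (mg m-3) is lognormal with the given log-scale parameters.
    """

    sst_mean: float = 28.5
    sst_seasonal_amp: float = 1.6
    sst_peak_month: int = 6
    sst_lat_gradient: float = -0.2  # degC per degree latitude (warmer south)
    sst_noise_sigma: float = 0.3
    sst_clip: tuple[float, float] = (25.0, 32.0)
    ssta_offset: float = 1.0
    ssta_sigma: float = 0.9
    chl_log_mean: float = float(np.log(0.12))
    chl_log_sigma: float = 0.35
    smooth_cells: float = 2.0  # isotropic Gaussian-filter radius, in cells


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth Gaussian response parameters driving vessel placement.

    ``responses`` maps factor name -> (optimum, curvature); the expected
    vessel count in a cell is ``base_intensity * prod_f exp(-k_f (x_f - b_f)^2)``.
    ``field_noise_sigma`` optionally multiplies the environmental fields seen
    by the placement model with lognormal noise.
    """

    responses: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sst": (29.0, 1.0),
            "ssta": (1.0, 2.0),
            "chl": (0.12, 150.0),
        }
    )
    base_intensity: float = 3.0
    field_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name, (b, k) in self.responses.items():
            if not np.isfinite(b):
                raise ValueError(f"{name}: optimum must be finite")
            if k <= 0:
                raise ValueError(f"{name}: curvature must be positive, got {k}")
        if self.base_intensity < 0:
            raise ValueError("base_intensity must be non-negative")
        if self.field_noise_sigma < 0:
            raise ValueError("field_noise_sigma must be non-negative")

    def response(self, factor: str, x: np.ndarray) -> np.ndarray:
        b, k = self.responses[factor]
        return np.exp(-k * (np.asarray(x, dtype=float) - b) ** 2)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float, smooth: float) -> np.ndarray:
    """Zero-mean spatially smooth noise with marginal standard deviation sigma."""
    if sigma == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if smooth > 0:
        sm = gaussian_filter(white, smooth, mode="nearest")
        sd = sm.std()
        if sd > 0:
            sm = sm / sd
        return sigma * sm
    return sigma * white


def _parse_period(period: str) -> tuple[int, int]:
    year, month = period.split("-")
    y, m = int(year), int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"bad period {period!r}: month out of range")
    return y, m


def _sst_climatology(grid: GridSpec, month: int, cfg: FieldConfig) -> np.ndarray:
    seasonal = cfg.sst_seasonal_amp * np.cos(2 * np.pi * (month - cfg.sst_peak_month) / 12.0)
    lat = grid.lat_centers[:, None] - 0.5 * (grid.lat_min + grid.lat_max)
    return cfg.sst_mean + seasonal + cfg.sst_lat_gradient * lat * np.ones((1, grid.n_lon))


def generate_env_fields(
    grid: GridSpec = DEFAULT_REGION,
    periods: list[str] | tuple[str, ...] = ("2016-03", "2016-06", "2016-09", "2016-12"),
    cfg: FieldConfig = FieldConfig(),
    seed: int = 0,
    daily: bool = False,
) -> dict[str, dict[str, RasterField]]:
    """Generate co-registered SST/SSTA/CHL fields for each period.

    Periods are ``"YYYY-MM"`` month labels. With ``daily=True`` the outer keys
    are ISO dates covering every day of each month (daily fields share the
    month's climatology and differ by noise), suitable for testing temporal
    composition.
    """
    if not periods:
        raise ValueError("period list must be non-empty")
    root = np.random.SeedSequence(seed)
    out: dict[str, dict[str, RasterField]] = {}
    for period, child in zip(periods, root.spawn(len(periods))):
        y, m = _parse_period(period)
        clim = _sst_climatology(grid, m, cfg)
        if daily:
            ndays = calendar.monthrange(y, m)[0:2][1]
            day_seeds = child.spawn(ndays)
            for d in range(1, ndays + 1):
                label = f"{y:04d}-{m:02d}-{d:02d}"
                out[label] = _one_period(grid, label, clim, cfg, np.random.default_rng(day_seeds[d - 1]))
        else:
            out[period] = _one_period(grid, period, clim, cfg, np.random.default_rng(child))
    return out


def _one_period(
    grid: GridSpec,
    label: str,
    sst_clim: np.ndarray,
    cfg: FieldConfig,
    rng: np.random.Generator,
) -> dict[str, RasterField]:
    shape = grid.shape
    sst = sst_clim + _smooth_noise(rng, shape, cfg.sst_noise_sigma, cfg.smooth_cells)
    sst = np.clip(sst, *cfg.sst_clip)
    ssta = cfg.ssta_offset + _smooth_noise(rng, shape, cfg.ssta_sigma, cfg.smooth_cells)
    chl = np.exp(cfg.chl_log_mean + _smooth_noise(rng, shape, cfg.chl_log_sigma, cfg.smooth_cells))
    return {
        "sst": RasterField(grid, label, "sst", "degC", sst),
        "ssta": RasterField(grid, label, "ssta", "degC", ssta),
        "chl": RasterField(grid, label, "chl", "mg m-3", chl),
    }


def expected_intensity(env: dict[str, RasterField], truth: TruthParams) -> np.ndarray:
    """Expected vessel count per cell: base intensity times the product of
    the Gaussian responses to each factor present in the truth."""
    lam = np.full(next(iter(env.values())).grid.shape, truth.base_intensity)
    for factor, (b, k) in truth.responses.items():
        if factor in env:
            lam = lam * truth.response(factor, env[factor].values)
    return lam


def generate_vessel_records(
    env_by_period: dict[str, dict[str, RasterField]],
    truth: TruthParams = TruthParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw vessel records from an inhomogeneous Poisson process over cells.

    Each cell-period count is Poisson with mean ``base_intensity`` times the
    product of Gaussian responses; each drawn vessel gets a unique id, a
    uniform random position inside its cell and a uniform random day within
    the period month. Returns a table with columns vessel_id, datetime, lon,
    lat (empty, with a warning, if the intensity is zero everywhere).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[tuple[str, str, float, float]] = []
    vessel_no = 0
    any_intensity = False
    for period in sorted(env_by_period):
        env = env_by_period[period]
        grid = next(iter(env.values())).grid
        for factor in truth.responses:
            if factor in env:
                b, _ = truth.responses[factor]
                vals = env[factor].values
                if not (np.nanmin(vals) <= b <= np.nanmax(vals)):
                    warnings.warn(
                        f"{period}: optimum {b} for {factor!r} lies outside the "
                        f"field range [{np.nanmin(vals):.3g}, {np.nanmax(vals):.3g}]",
                        stacklevel=2,
                    )
        lam = expected_intensity(env, truth)
        lam = np.nan_to_num(lam, nan=0.0)
        if lam.max() > 0:
            any_intensity = True
        counts = rng.poisson(lam)
        y, m = _parse_period(period)
        ndays = calendar.monthrange(y, m)[1]
        occ_rows, occ_cols = np.nonzero(counts)
        for r, c in zip(occ_rows, occ_cols):
            n = int(counts[r, c])
            lon0 = grid.lon_min + c * grid.cell_size
            lat0 = grid.lat_min + r * grid.cell_size
            lons = lon0 + rng.random(n) * grid.cell_size
            lats = lat0 + rng.random(n) * grid.cell_size
            days = rng.integers(1, ndays + 1, size=n)
            for i in range(n):
                vessel_no += 1
                rows.append(
                    (
                        f"V{vessel_no:06d}",
                        f"{y:04d}-{m:02d}-{int(days[i]):02d}T20:00:00",
                        float(lons[i]),
                        float(lats[i]),
                    )
                )
    if not any_intensity:
        warnings.warn("vessel intensity is zero everywhere; returning empty table", stacklevel=2)
    return pd.DataFrame(rows, columns=["vessel_id", "datetime", "lon", "lat"])


def generate_survey_field(
    env: dict[str, RasterField],
    truth: TruthParams = TruthParams(),
    seed: int = 0,
    noise_sigma: float = 0.1,
    coverage: float = 0.6,
) -> RasterField:
    """Stand-in acoustic-survey observation layer (synthetic).

    The observed value per surveyed cell is the normalized truth response plus
    Gaussian noise, clipped to [0, 1]; a random subset of cells of the given
    coverage fraction is surveyed, the rest are missing — mimicking a survey
    track that does not visit every cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lam = expected_intensity(env, truth)
    peak = np.nanmax(lam)
    obs = lam / peak if peak > 0 else np.zeros_like(lam)
    obs = np.clip(obs + rng.normal(0.0, noise_sigma, obs.shape), 0.0, 1.0)
    not_surveyed = rng.random(obs.shape) > coverage
    obs[not_surveyed] = np.nan
    grid = next(iter(env.values())).grid
    period = next(iter(env.values())).period
    return RasterField(grid, period, "survey_si", "1", obs)


def inject_missing(field: RasterField, fraction: float, seed: int = 0) -> RasterField:
    """Flag exactly ``round(fraction * n_cells)`` cells as missing.

    Only currently observed cells are knocked out; remaining values are
    untouched. ``fraction`` must lie in [0, 1).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n_gap = round(fraction * field.values.size)
    out = field.copy()
    if n_gap == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flat_obs = np.flatnonzero(~field.missing_mask.ravel())
    if n_gap > len(flat_obs):
        raise ValueError("cannot inject more gaps than observed cells")
    kill = rng.choice(flat_obs, size=n_gap, replace=False)
    flat = out.values.ravel()
    flat[kill] = np.nan
    out.values = flat.reshape(field.grid.shape)
    return out
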