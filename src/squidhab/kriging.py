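"""Ordinary-kriging gap fill for gridded environmental fields.

Missing cells are estimated from observed cells by ordinary kriging with an
exponential variogram fitted by the method of moments (15 distance bins,
nugget allowed). With fewer than 5 observed cells the estimator degrades
gracefully to inverse-distance weighting; with none it raises.

Distances are Euclidean in degrees — adequate over regional boxes where the
grid itself is a plate-carree lattice.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.linalg import solve
from scipy.spatial.distance import cdist

from .grids import RasterField

__all__ = ["fill_missing", "fit_exponential_variogram", "empirical_variogram"]

log = logging.getLogger(__name__)

_N_BINS = 15
_MAX_PAIR_POINTS = 1500  # subsample observed points beyond this for the variogram


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = _N_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments semivariogram: bin centres and gamma estimates.

    gamma(h) = mean over pairs in the bin of 0.5 * (z_i - z_j)^2, binned on
    pair distance up to half the maximum pair distance.
    """
    n = len(values)
    if n > _MAX_PAIR_POINTS:
        idx = np.random.default_rng(0).choice(n, _MAX_PAIR_POINTS, replace=False)
        coords, values = coords[idx], values[idx]
        n = _MAX_PAIR_POINTS
    iu = np.triu_indices(n, k=1)
    d = cdist(coords, coords)[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    h_max = d.max() / 2.0
    edges = np.linspace(0.0, h_max, n_bins + 1)
    which = np.digitize(d, edges) - 1
    centers, gammas = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() >= 2:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            gammas.append(sq[m].mean())
    return np.asarray(centers), np.asarray(gammas)


def _exp_model(h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    return nugget + psill * (1.0 - np.exp(-h / rng))


def fit_exponential_variogram(
    coords: np.ndarray, values: np.ndarray
) -> tuple[float, float, float]:
    """Fit (nugget, partial sill, range) of an exponential variogram model."""
    h, g = empirical_variogram(coords, values)
    if len(h) < 3 or np.allclose(g, 0.0):
        # flat field: any tiny variogram keeps the kriging system well posed
        return 0.0, max(float(np.var(values)), 1e-12), float(h.max() if len(h) else 1.0)
    p0 = (0.0, max(g.max(), 1e-12), max(h.max() / 2.0, 1e-6))
    bounds = ([0.0, 1e-12, 1e-9], [g.max() + 1e-12, 10.0 * g.max() + 1e-9, 100.0 * h.max()])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_exp_model, h, g, p0=p0, bounds=bounds, maxfev=20000)
        return float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError:
        log.warning("variogram fit failed to converge; using moment estimates")
        return 0.0, float(g.max()), float(h.max() / 2.0)


def _idw(obs_xy: np.ndarray, obs_z: np.ndarray, tgt_xy: np.ndarray, power: float = 2.0) -> np.ndarray:
    d = cdist(tgt_xy, obs_xy)
    d = np.maximum(d, 1e-12)
    w = d ** (-power)
    return (w @ obs_z) / w.sum(axis=1)


def fill_missing(field: RasterField, clip_tolerance: float = 0.05) -> RasterField:
    """Fill missing cells of a field by ordinary kriging.

    Observed cells are passed through unchanged (the method is an exact
    interpolator, and idempotent on fully observed fields). Filled values are
    clipped to the observed range widened by ``clip_tolerance`` times the
    observed spread on each side.

    Falls back to inverse-distance weighting (with a warning) when fewer than
    5 cells are observed; raises when none are.
    """
    miss = field.missing_mask
    if not miss.any():
        return field.copy()

    lon_c, lat_c = np.meshgrid(field.grid.lon_centers, field.grid.lat_centers)
    obs = ~miss
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("cannot fill a field with no observed cells")

    obs_xy = np.column_stack([lon_c[obs], lat_c[obs]])
    obs_z = field.values[obs]
    tgt_xy = np.column_stack([lon_c[miss], lat_c[miss]])

    if n_obs < 5:
        warnings.warn(
            f"only {n_obs} observed cells: falling back to inverse-distance weighting",
            stacklevel=2,
        )
        filled = _idw(obs_xy, obs_z, tgt_xy)
    else:
        nugget, psill, rng = fit_exponential_variogram(obs_xy, obs_z)
        gamma_oo = _exp_model(cdist(obs_xy, obs_xy), nugget, psill, rng)
        np.fill_diagonal(gamma_oo, 0.0)
        a = np.empty((n_obs + 1, n_obs + 1))
        a[:n_obs, :n_obs] = gamma_oo
        a[n_obs, :] = 1.0
        a[:, n_obs] = 1.0
        a[n_obs, n_obs] = 0.0
        # slight diagonal jitter guards against singular systems on lattices
        a[:n_obs, :n_obs] += np.eye(n_obs) * 1e-10
        b = np.empty((n_obs + 1, len(tgt_xy)))
        b[:n_obs] = _exp_model(cdist(obs_xy, tgt_xy), nugget, psill, rng)
        b[n_obs] = 1.0
        w = solve(a, b, assume_a="sym")[:n_obs]
        filled = w.T @ obs_z

    spread = obs_z.max() - obs_z.min()
    lo = obs_z.min() - clip_tolerance * spread
    hi = obs_z.max() + clip_tolerance * spread
    filled = np.clip(filled, lo, hi)

    out = field.copy()
    out.values[miss] = filled
    log.info("fill_missing: filled %d of %d cells", int(miss.sum()), miss.size)
    return out
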