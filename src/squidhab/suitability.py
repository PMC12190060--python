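"""Single-factor suitability-index (SI) curves.

SI observations are built by binning cells on an environmental variable,
summing normalized effort (CPUE) per bin, and scaling by the maximum bin sum
so the best bin scores exactly 1. The unimodal environmental response is then
modelled as a Gaussian curve

    SI(x) = exp(-k (x - b)^2),    k > 0,

with optimum ``b`` (the preferred value of the variable) and curvature ``k``
(1/units^2; larger k means a narrower niche). Fitting is nonlinear least
squares on the original SI scale; a log-linearized quadratic regression on
the positive-SI points supplies the starting values. The fitted curve is
reported with the conventional nonlinear-regression ANOVA statistics
(R^2, F with (1, n-2) degrees of freedom, and its p value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .effort import CPUEField
from .grids import RasterField

__all__ = [
    "BinSpec",
    "SIObservation",
    "GaussianSIFit",
    "DEFAULT_BIN_WIDTHS",
    "bin_si",
    "fit_si",
    "si_predict",
    "si_range",
]

#: default environmental bin widths by variable.
DEFAULT_BIN_WIDTHS = {"sst": 0.2, "ssta": 0.1, "chl": 0.01}


@dataclass(frozen=True)
class BinSpec:
    """Half-open environmental bins ``[lo, hi)`` for one variable."""

    variable: str
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 5:
            raise ValueError("need at least 4 bins (5 edges)")
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def regular(cls, variable: str, lo: float, hi: float, width: float | None = None) -> "BinSpec":
        """Equal-width bins covering [lo, hi] using the variable's default width."""
        if width is None:
            width = DEFAULT_BIN_WIDTHS.get(variable, (hi - lo) / 20.0)
        start = math.floor(lo / width) * width
        n = max(4, math.ceil((hi - start) / width + 1e-9))
        edges = start + width * np.arange(n + 1)
        return cls(variable, tuple(edges))

    @classmethod
    def quantile(cls, variable: str, values: np.ndarray, n_bins: int = 12) -> "BinSpec":
        """Equal-count bins from observed values (alternative to fixed widths)."""
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        qs = np.quantile(v, np.linspace(0, 1, n_bins + 1))
        qs[-1] = np.nextafter(qs[-1], np.inf)  # include the max in the top bin
        edges = np.unique(qs)
        if len(edges) < 5:
            raise ValueError("too few distinct values for quantile binning")
        return cls(variable, tuple(edges))

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class SIObservation:
    """SI for one environmental bin: the bin's summed CPUE relative to the
    best bin, with the bin centre as the predictor value."""

    center: float
    si: float
    total_cpue: float
    n_cells: int


@dataclass(frozen=True)
class GaussianSIFit:
    """Fitted Gaussian response exp(-k (x - b)^2) with fit statistics.

    ``a = -k`` is the signed coefficient as conventionally printed with the
    fitted equation.
    """

    variable: str
    optimum: float  # b, variable units
    curvature: float  # k > 0, 1/units^2
    n: int
    r_squared: float
    f_stat: float
    p_value: float
    converged: bool

    @property
    def a(self) -> float:
        return -self.curvature

    @property
    def b(self) -> float:
        return self.optimum


def bin_si(
    cpue_fields: CPUEField | list[CPUEField],
    env_fields: RasterField | list[RasterField],
    bins: BinSpec,
) -> list[SIObservation]:
    """Build SI observations by summing CPUE within environmental bins.

    Accepts one field pair or parallel lists of co-registered pairs (e.g. the
    same season across several years pooled into one curve). Cells missing in
    either member of a pair are skipped; bins with no cells are excluded.
    """
    if isinstance(cpue_fields, CPUEField):
        cpue_fields = [cpue_fields]
    if isinstance(env_fields, RasterField):
        env_fields = [env_fields]
    if len(cpue_fields) != len(env_fields):
        raise ValueError("cpue and env field lists must be parallel")

    xs, ws = [], []
    for cf, ef in zip(cpue_fields, env_fields):
        if cf.grid != ef.grid:
            raise ValueError("cpue and env fields must share one grid")
        valid = ~(cf.missing_mask | ef.missing_mask)
        xs.append(ef.values[valid])
        ws.append(cf.values[valid])
    x = np.concatenate(xs)
    w = np.concatenate(ws)

    edges = np.asarray(bins.edges)
    if x.size and (x.min() < edges[0] or x.max() >= edges[-1]):
        raise ValueError(
            f"bins [{edges[0]:g}, {edges[-1]:g}) do not cover the observed "
            f"range [{x.min():g}, {x.max():g}]"
        )
    which = np.digitize(x, edges) - 1
    sums = np.bincount(which, weights=w, minlength=len(edges) - 1)
    counts = np.bincount(which, minlength=len(edges) - 1)

    occupied = counts > 0
    max_sum = sums[occupied].max() if occupied.any() else 0.0
    if max_sum <= 0:
        raise ValueError("no CPUE mass in any bin")
    if (sums > 0).sum() == 1:
        warnings.warn("all CPUE mass falls in a single bin; the SI fit will be degenerate", stacklevel=2)

    return [
        SIObservation(
            center=float(bins.centers[i]),
            si=float(sums[i] / max_sum),
            total_cpue=float(sums[i]),
            n_cells=int(counts[i]),
        )
        for i in np.flatnonzero(occupied)
    ]


def _gauss(x: np.ndarray, k: float, b: float) -> np.ndarray:
    return np.exp(-k * (x - b) ** 2)


def _log_linear_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Quadratic regression of ln SI on x over positive-SI points; returns
    (k, b) when the quadratic opens downward, else None."""
    pos = y > 0
    if pos.sum() < 3:
        return None
    c2, c1, _ = np.polyfit(x[pos], np.log(y[pos]), 2)
    if c2 >= 0:
        return None
    k = -c2
    return float(k), float(c1 / (2.0 * k))


def fit_si(
    obs: list[SIObservation],
    variable: str = "",
    include_zeros: bool = True,
) -> GaussianSIFit:
    """Least-squares fit of the Gaussian SI curve to binned observations.

    Minimizes sum(SI - exp(-k (x - b)^2))^2 on the original SI scale.
    Zero-SI bins are kept by default (they pin down the curve's tails);
    ``include_zeros=False`` drops them. Raises on degenerate input (fewer
    than 4 points, constant SI) and when no unimodal fit exists (k <= 0 at
    every optimum across a grid of restarts).
    """
    if len(obs) < 4:
        raise ValueError(f"need at least 4 SI observations, got {len(obs)}")
    x = np.array([o.center for o in obs], dtype=float)
    y = np.array([o.si for o in obs], dtype=float)
    if not include_zeros:
        keep = y > 0
        x, y = x[keep], y[keep]
        if len(x) < 4:
            raise ValueError("fewer than 4 non-zero SI observations")
    if np.ptp(y) == 0:
        raise ValueError("SI values are all equal; response curve is undefined")

    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    starts: list[tuple[float, float]] = []
    init = _log_linear_init(x, y)
    if init is not None and init[0] > 0:
        starts.append(init)
    x_peak = float(x[np.argmax(y)])
    for k0 in (0.5 / span**2, 4.0 / span**2, 32.0 / span**2, 256.0 / span**2):
        starts.append((k0, x_peak))

    best: tuple[float, float, float] | None = None  # (ssres, k, b)
    converged = False
    for k0, b0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _gauss, x, y, p0=(k0, b0), maxfev=20000,
                    bounds=([1e-12, x.min() - 10 * span], [np.inf, x.max() + 10 * span]),
                )
        except RuntimeError:
            continue
        k, b = float(popt[0]), float(popt[1])
        ssres = float(np.sum((y - _gauss(x, k, b)) ** 2))
        if best is None or ssres < best[0]:
            best = (ssres, k, b)
            converged = True
    if best is None:
        raise RuntimeError("Gaussian SI fit failed to converge from every start")
    ssres, k, b = best
    if k <= 0:
        raise ValueError("fitted curvature is non-positive; response is not unimodal")

    n = len(x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssreg = max(sstot - ssres, 0.0)
    r2 = 1.0 - ssres / sstot if sstot > 0 else float("nan")
    if ssres <= 0:
        f = float("inf")
        p = 0.0
    else:
        f = (ssreg / 1.0) / (ssres / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
    return GaussianSIFit(variable, b, k, n, r2, f, p, converged)


def si_predict(fit: GaussianSIFit, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted response: exp(-k (x - b)^2), in (0, 1]."""
    out = np.exp(-fit.curvature * (np.asarray(x, dtype=float) - fit.optimum) ** 2)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def si_range(fit: GaussianSIFit, threshold: float = 0.6, decimals: int = 2) -> tuple[float, float]:
    """Environmental interval where predicted SI meets the threshold.

    Solves exp(-k (x - b)^2) = threshold in closed form:
    b +/- sqrt(ln(1/threshold) / k), rounded to ``decimals`` places.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    half_width = math.sqrt(math.log(1.0 / threshold) / fit.curvature)
    return (
        round(fit.optimum - half_width, decimals),
        round(fit.optimum + half_width, decimals),
    )
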