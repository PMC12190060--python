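"""Composite habitat suitability: HSI fields, grading, accuracy scoring and
the six-scheme resolution comparison.

The habitat suitability index is the geometric mean of the three single-factor
suitability indices (SST, SST anomaly, chlorophyll-a), graded into four equal
bands. Model skill is the fraction of cells whose predicted HSI lies strictly
within 0.3 of the observed normalized effort; scheme comparison reruns the
whole pipeline at each (spatial, temporal) resolution and ranks schemes by
the unweighted mean of their per-period accuracies.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effort import CPUEField, cpue
from .gridding import aggregate_field, aggregate_vessels
from .grids import GridSpec, RasterField, Scheme, SCHEMES, TemporalScale
from .suitability import BinSpec, GaussianSIFit, bin_si, fit_si, si_predict

__all__ = [
    "HSIField",
    "GradeField",
    "AccuracyReport",
    "GRADE_LABELS",
    "combine_hsi",
    "fit_seasonal_sst_hsi",
    "classify",
    "accuracy",
    "mean_accuracy",
    "run_scheme_comparison",
]

log = logging.getLogger(__name__)

GRADE_LABELS = ("unsuitable", "generally suitable", "suitable", "most suitable")

#: grade band edges: [0,.25) / [.25,.5) / [.5,.75) / [.75,1]; each boundary
#: belongs to the class above it.
GRADE_EDGES = (0.25, 0.5, 0.75)


@dataclass
class HSIField:
    """Composite habitat suitability in [0, 1] per cell."""

    grid: GridSpec
    period: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class GradeField:
    """Per-cell habitat grade codes (0-3) with shared labels."""

    grid: GridSpec
    period: str
    codes: np.ndarray  # int codes, -1 for missing

    def labels(self) -> np.ndarray:
        out = np.full(self.codes.shape, "missing", dtype=object)
        for code, label in enumerate(GRADE_LABELS):
            out[self.codes == code] = label
        return out


@dataclass(frozen=True)
class AccuracyReport:
    """Cells within the 0.3 prediction band, out of all comparable cells."""

    correct: int
    total: int
    scheme_id: int | None = None
    period: str | None = None

    @property
    def accuracy_pct(self) -> float:
        return round(100.0 * self.correct / self.total, 3)


def combine_hsi(
    si_sst: np.ndarray | RasterField,
    si_ssta: np.ndarray | RasterField,
    si_chl: np.ndarray | RasterField,
    grid: GridSpec | None = None,
    period: str = "",
) -> HSIField:
    """Cellwise geometric mean of the three single-factor SI fields.

    Exactly zero wherever any factor is zero; always bounded by the cellwise
    min and max of the factors.
    """
    arrays = []
    for f in (si_sst, si_ssta, si_chl):
        if isinstance(f, RasterField):
            grid = grid or f.grid
            period = period or f.period
            arrays.append(f.values)
        else:
            arrays.append(np.asarray(f, dtype=float))
    if grid is None:
        raise ValueError("grid must be supplied when passing bare arrays")
    a, b, c = arrays
    for arr in arrays:
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("SI values must lie in [0, 1]")
    return HSIField(grid, period, np.cbrt(a * b * c))


def fit_seasonal_sst_hsi(
    cpue_fields: CPUEField | list[CPUEField],
    sst_fields: RasterField | list[RasterField],
    bins: BinSpec | None = None,
) -> GaussianSIFit:
    """Empirical single-factor seasonal HSI model driven by SST alone.

    Bins the season's pooled cells on SST, normalizes to the best bin, and
    fits the Gaussian response; the fitted curve is then used directly as the
    HSI prediction for scenario work.
    """
    sst_list = [sst_fields] if isinstance(sst_fields, RasterField) else list(sst_fields)
    if bins is None:
        lo = min(float(np.nanmin(f.values)) for f in sst_list)
        hi = max(float(np.nanmax(f.values)) for f in sst_list)
        bins = BinSpec.regular("sst", lo, hi)
    obs = bin_si(cpue_fields, sst_fields, bins)
    return fit_si(obs, variable="sst")


def classify(hsi: HSIField) -> GradeField:
    """Grade HSI into four equal bands at 0.25/0.5/0.75.

    Each boundary belongs to the class above it (0.25 is already "generally
    suitable"); 1.0 stays "most suitable". Out-of-range values are rejected.
    """
    v = hsi.values
    finite = v[~np.isnan(v)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("HSI values must lie in [0, 1]")
    codes = np.digitize(v, GRADE_EDGES)  # boundary -> upper class
    codes = np.where(np.isnan(v), -1, codes).astype(int)
    return GradeField(hsi.grid, hsi.period, codes)


def accuracy(
    pred: HSIField,
    obs: CPUEField,
    band: float = 0.3,
    scheme_id: int | None = None,
) -> AccuracyReport:
    """Score predictions against observed normalized effort.

    A cell counts as correct when ``|pred - obs| < band`` (strictly: a
    deviation of exactly 0.3 is incorrect). Cells missing in either field are
    excluded and logged.
    """
    if pred.grid != obs.grid:
        raise ValueError("prediction and observation grids differ")
    ok = ~(pred.missing_mask | obs.missing_mask)
    total = int(ok.sum())
    if total == 0:
        raise ValueError("no comparable cells")
    n_skip = ok.size - total
    if n_skip:
        log.info("accuracy: excluded %d cells with missing values", n_skip)
    correct = int((np.abs(pred.values[ok] - obs.values[ok]) < band).sum())
    return AccuracyReport(correct, total, scheme_id=scheme_id, period=pred.period)


def mean_accuracy(period_accuracies: list[float]) -> float:
    """Scheme-level score: the unweighted mean of per-period accuracies
    (not a pooled-cell accuracy), rounded to 3 decimals."""
    return round(float(np.mean(period_accuracies)), 3)


def _compose_env_periods(
    env_monthly: dict[str, dict[str, RasterField]],
    grid: GridSpec,
    temporal: TemporalScale,
) -> dict[str, dict[str, RasterField]]:
    """Aggregate monthly env fields to the scheme grid and pool months into
    the scheme's periods (equal-weight mean across contributing months)."""
    pooled: dict[str, dict[str, list[np.ndarray]]] = defaultdict(lambda: defaultdict(list))
    for label, fields in env_monthly.items():
        month = int(label.split("-")[1]) if "-" in label else int(label)
        period = temporal.period_of(month)
        if period is None:
            continue
        for var, fld in fields.items():
            coarse = fld if fld.grid == grid else aggregate_field(fld, grid)
            pooled[period][var].append(coarse.values)
    out: dict[str, dict[str, RasterField]] = {}
    sample = next(iter(env_monthly.values()))
    for period, by_var in pooled.items():
        out[period] = {}
        for var, stack in by_var.items():
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(np.stack(stack), axis=0)
            out[period][var] = RasterField(grid, period, var, sample[var].units, mean)
    return out


def run_scheme_comparison(
    records: pd.DataFrame,
    env_monthly: dict[str, dict[str, RasterField]],
    schemes: tuple[Scheme, ...] = SCHEMES,
    count_mode: str = "distinct",
    band: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, Scheme | None]:
    """Rebuild and score the HSI model under each (spatial, temporal) scheme.

    For each scheme the full pipeline runs: vessel counting on the scheme
    grid, CPUE normalization, per-period single-factor SI fits for the three
    variables, geometric-mean HSI, and the 0.3-band accuracy against the
    observed CPUE. Returns (per-period accuracy table, per-scheme summary
    with the unweighted mean accuracy, winning scheme). A scheme whose fits
    fail is recorded as failed and the comparison continues.
    """
    base_grid = next(iter(next(iter(env_monthly.values())).values())).grid
    rows: list[dict] = []
    summaries: list[dict] = []
    for scheme in schemes:
        grid = base_grid.with_cell_size(scheme.cell_size)
        temporal = scheme.temporal
        try:
            env = _compose_env_periods(env_monthly, grid, temporal)
            counts = aggregate_vessels(records, grid, temporal, count_mode=count_mode)
            period_accs = []
            for period in sorted(counts):
                if period not in env:
                    continue
                cp = cpue(counts[period])
                si_maps = {}
                for var in ("sst", "ssta", "chl"):
                    ef = env[period][var]
                    lo, hi = float(np.nanmin(ef.values)), float(np.nanmax(ef.values))
                    bins = BinSpec.regular(var, lo, hi)
                    fit = fit_si(bin_si(cp, ef, bins), variable=var)
                    si_maps[var] = si_predict(fit, ef.values)
                pred = combine_hsi(
                    si_maps["sst"], si_maps["ssta"], si_maps["chl"],
                    grid=grid, period=period,
                )
                rep = accuracy(pred, cp, band=band, scheme_id=scheme.scheme_id)
                period_accs.append(rep.accuracy_pct)
                rows.append(
                    {
                        "scheme_id": scheme.scheme_id,
                        "scheme": scheme.label(),
                        "period": period,
                        "correct": rep.correct,
                        "total": rep.total,
                        "accuracy_pct": rep.accuracy_pct,
                    }
                )
            if not period_accs:
                raise RuntimeError("no scorable periods")
            summaries.append(
                {
                    "scheme_id": scheme.scheme_id,
                    "scheme": scheme.label(),
                    "n_periods": len(period_accs),
                    "mean_accuracy_pct": mean_accuracy(period_accs),
                    "failed": False,
                }
            )
        except Exception as exc:  # scheme failure must not abort the comparison
            log.warning("scheme %s failed: %s", scheme.label(), exc)
            summaries.append(
                {
                    "scheme_id": scheme.scheme_id,
                    "scheme": scheme.label(),
                    "n_periods": 0,
                    "mean_accuracy_pct": float("nan"),
                    "failed": True,
                }
            )
    per_period = pd.DataFrame(rows)
    summary = pd.DataFrame(summaries)
    ok = summary[~summary["failed"]]
    winner = None
    if not ok.empty:
        best_id = int(ok.loc[ok["mean_accuracy_pct"].idxmax(), "scheme_id"])
        winner = next(s for s in schemes if s.scheme_id == best_id)
    return per_period, summary, winner
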