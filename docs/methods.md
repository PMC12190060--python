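# Methods

## Effort as a habitat signal

The package treats the spatial density of light falling-net fishing vessels
as a proxy for relative squid abundance. The assumptions are: (i) the fleet
is free to move and concentrates where catches are good, so vessel counts
track habitat quality up to a monotone transform; (ii) normalizing each
period by its busiest cell (`CPUE_i = BOAT_i / BOAT_max`) removes
fleet-size and seasonal-effort effects, leaving a [0, 1] relative field;
(iii) the response of that field to each environmental variable is unimodal.
These are working assumptions, not guarantees — moratoria, weather and fuel
prices also move fleets, which is one reason accuracy is scored rather than
assumed.

`BOAT_max` is taken per period per grid resolution, not globally: the
suitability index is re-normalized within each scheme anyway, so a global
maximum would only leak effort trends across years into the spatial signal.

"Number of vessels" in a cell-period defaults to distinct vessel ids
(`count_mode="distinct"`); a vessel pinging 10 times in one cell in a month
counts once, and a vessel visiting two cells counts in both. The alternative
`vessel_days` counts distinct (vessel, day) pairs. Distinct ids are the
default because repeated pings are a property of the transponder, not of the
habitat; the switch exists because monthly activity shares only sum to 100%
under vessel-days accounting.

## Grids, periods and conventions

Grids are plate-carrée boxes with half-open cells `[lo, hi)` labelled by
their lower-left corner, so a point on a shared edge belongs to exactly one
cell. A small relative epsilon (1e-9 of a cell) in the point-locator keeps
edge points from being dropped into the lower cell by floating-point
division error — 1e-9 degrees is ~0.1 mm, far below any positioning noise.

Seasons default to meteorological three-month blocks (spring = Mar–May, …,
winter = Dec–Feb, spanning the year boundary). A `representative` mode keeps
only March/June/September/December, one month per season, for analyses built
on representative months. Whether a seasonal model should pool all three
months or only the representative month is genuinely open; both modes are
first-class and the scheme comparison uses full pooling.

Coarsening is block-averaging over nested grids (coarse cell = mean of
non-missing fine cells; missing only if all constituents are missing), and
period means over daily fields are day-weighted. For equal-weight nesting,
one-step and two-step aggregation agree exactly.

## Kriging gap fill

Missing cells in environmental fields are filled by ordinary kriging:
method-of-moments empirical semivariogram on 15 distance bins (up to half
the maximum pair distance), an exponential model `γ(h) = c₀ + c₁(1 −
exp(−h/r))` fitted by bounded least squares (nugget c₀ allowed), and one
global kriging system solved for all targets. Distances are Euclidean in
degrees, adequate for regional boxes at these latitudes. Below 5 observed
cells the estimator falls back to inverse-distance weighting with a warning;
with none it raises. Filled values are clipped to the observed range widened
by 5% of the observed spread per side — kriging weights can be mildly
extrapolative at field corners, and unconstrained overshoot is physically
meaningless for SST or CHL. Observed cells always pass through unchanged, so
the operation is idempotent on complete fields. On smooth fields the fill is
near-exact (on a planar field with 10% gaps the maximum error is well under
1% of the field range); on pure-nugget noise it degrades gracefully toward
the local mean, which is the right behaviour for a gap-filler.

## Suitability curves

SI observations are built per environmental bin: half-open bins of default
width 0.2 °C (SST), 0.1 °C (SSTA) and 0.01 mg·m⁻³ (CHL) — wide enough to
fill at the sample sizes involved, narrow enough to resolve curvatures of
order 10–10⁴ in the respective units; an equal-count (quantile) alternative
exists for skewed variables. Each bin's summed CPUE over cells, divided by
the best bin's sum, is one observation; empty bins are excluded, zero-CPUE
bins are kept by default because they pin down the tails (a switch drops
them).

Note that the summed-CPUE statistic weights bins by how many cells carry
that environmental value; it estimates the response only up to the sampling
density of the variable. The per-cell response is recoverable from the
stored `total_cpue / n_cells`, which is what the convergence tests compare
against truth.

The Gaussian response `SI(x) = exp(−k(x − b)²)` is fitted by
Levenberg–Marquardt-style bounded least squares on the original SI scale
(not log scale, because zero-SI bins exist). Starting values come from a
quadratic regression of `ln SI` on `x` over the positive-SI points; if that
quadratic opens upward the fit restarts from a small grid of curvatures
(0.5/4/32/256 per squared data-span) centred on the empirical peak, and the
best converged candidate by residual sum of squares wins. A fit is rejected
when fewer than 4 observations exist, when all SI are equal, or when the
best curvature is non-positive (no unimodal response). Reported statistics
follow the standard one-parameter-regression ANOVA decomposition: R² = 1 −
SSres/SStot, F = SSreg / (SSres/(n−2)), p from F(1, n−2). The software used
in the original analyses may define F differently, so only the curve
parameters — not F or p — are treated as comparable across implementations.

The optimal range at level θ (default 0.6) is closed-form:
`b ± sqrt(ln(1/θ)/k)`, reported at 2 decimals.

## Composite HSI, grades and accuracy

HSI is the cellwise geometric mean of the three single-factor SIs; it is
exactly zero when any factor is zero and always lies between the cellwise
min and max of the factors. Grades cut [0, 1] at 0.25/0.5/0.75 with each
boundary belonging to the class above (the convention is configurable; the
grading source material is ambiguous at the top band and 0.75–1 is used for
"most suitable"). Accuracy compares predicted HSI with observed CPUE on the
same grid — CPUE is the only [0, 1] observable available — counting a cell
correct when |pred − obs| < 0.3, strictly; a deviation of exactly 0.3 is
incorrect. Scheme-level scores are unweighted means of per-period
accuracies, not pooled-cell accuracies: periods are the replication unit,
and pooling would let one heavily-fished season dominate the ranking.

Survey-based validation is the same accuracy operation applied to a
survey-derived observation grid; the synthetic module provides a stand-in
survey layer (truth response plus noise on a partial-coverage mask) for
testing that path.

## Scenarios

Scenario analysis adds a uniform delta (±0.2/±0.5/±1 °C by default, baseline
always included) to the seasonal baseline SST and repredicts HSI from the
seasonal SST-only Gaussian model. SSTA is held fixed rather than co-shifted:
a uniform SST offset with an unchanged climatology would shift SSTA
identically, but the scenario machinery deliberately probes the SST response
alone; a switch in the three-factor path allows co-shifting. Cell areas are
spherical: `R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371.0088 km. Three
classes are accounted: the suitable band (0.5 < HSI ≤ 0.75), optimal
(HSI > 0.75), and their union (HSI > 0.5); band + optimal = union exactly.
Area ratio uses the summed area of all analysed cells as denominator — the
ratio definition, not any particular region mask, is the method. When a
season's baseline area is zero, the change column reports the scenario's
area ratio instead of an undefined percentage; this is nonstandard and
deliberately prominent in the column documentation.

Two exact properties anchor the tests: shift equivariance (shifting the
field by δ equals shifting the model optimum by −δ), and the narrow-niche
collapse — a Gaussian model with curvature k admits HSI > 0.5 only within
`sqrt(ln 2 / k)` of its optimum (< 0.24 °C for k ≥ 12.95), so a ±1 °C shift
empties any field whose SST span lies inside the remaining margin.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, in a
tropical offshore box (default 109–117 °E, 6–12 °N at 0.1°, chosen so the
0.1/0.5/1° scheme grids nest exactly):

* **SST**: annual mean 28.5 °C + 1.6 °C sinusoidal cycle peaking in June +
  linear latitudinal gradient (−0.2 °C/° lat, warmer south) + smoothed
  Gaussian noise (σ = 0.3 °C, 2-cell filter), clipped to [25, 32] °C — a
  warm, weakly-graded tropical sea.
* **SSTA**: smoothed noise (σ = 0.9 °C) around a configurable offset
  (default +1 °C, so anomaly optima near 1 °C are representable).
* **CHL**: lognormal with median 0.12 mg·m⁻³ and log-σ 0.35, spanning
  roughly 0.05–0.3 mg·m⁻³, always positive.

Vessels are an inhomogeneous Poisson process over cells: expected count =
base intensity (default 3 vessels/cell-period) × a product of Gaussian
responses to the three fields (defaults: SST optimum 29 °C, k = 1; SSTA
optimum 1 °C, k = 2; CHL optimum 0.12 mg·m⁻³, k = 150). Each drawn vessel
gets a unique id, a uniform position in its cell and a uniform day in the
month. The Poisson choice is the generator's own: cell-level counts are all
the analysis consumes, so no trajectory model is attempted. The generator
warns when a truth optimum falls outside a generated field's range (common
for single seasons of the SST cycle, by construction).

All randomness flows from one integer seed through spawned NumPy
`SeedSequence` children; equal seeds give bit-identical outputs and no
global state is touched.

What the generator does *not* emulate — coastlines and bathymetry, currents
and fronts, moratorium-driven fleet displacement, spatially correlated
vessel behaviour, reporting gaps — bounds what green tests mean: they verify
the estimators recover known structure under the model's own assumptions,
not that the assumptions hold in any real fishery.

## Problem sizes in the test suite

Unit tests run on 10×10 to 40×40 cell grids with one to four periods. The
convergence study uses 50 vs 200 one-month periods at sparse effort (0.3
vessels/cell-period) so the shorter run is variance-limited rather than
sitting at the estimator's bin-discretization floor. The Monte-Carlo fit
recovery uses 200 replicates of 30-point curves at noise σ = 0.05. The
scheme-comparison study generates 20 synthetic fisheries whose environment
is piecewise-constant on 0.5° blocks and constant within seasons, and checks
the 0.5°-seasonal scheme wins far above the 1-in-6 chance rate.

## Known limitations

* Kriging solves one global system; for grids beyond ~50×50 with few gaps
  this is fine, but very large sparse fields would want a neighbourhood
  limit.
* The summed-CPUE SI estimator is occupancy-weighted (see above); curves
  fitted to it inherit the sampling density of the environmental variable.
* CPUE from vessel counts saturates in the busiest cell by construction
  (value 1 regardless of how busy), compressing the top of the response.
* Plate-carrée bookkeeping only; no projections, shoreline masks or
  land/sea awareness.
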