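# squidhab

Multi-scale habitat suitability modelling for light falling-net squid
fisheries, built for fisheries oceanographers working with vessel-monitoring
(VMS) effort data and gridded sea-surface environmental fields.

The purpleback flying squid (*Sthenoteuthis oualaniensis*) is the main target
of the light falling-net fleet in the Nansha offshore area of the South China
Sea. Because the fleet aggregates where squid aggregate, the spatial density
of fishing vessels is a usable proxy for habitat quality. `squidhab` turns
vessel position records and daily sea-surface fields — temperature (SST), its
anomaly (SSTA) and chlorophyll-a (CHL) — into suitability curves, composite
habitat maps, a resolution-scheme comparison, and temperature-shift scenario
area tables, and ships a synthetic-data generator so the entire pipeline is
testable without any proprietary data.

## The model

Effort is normalized per period and grid into a catch-per-unit-effort proxy

    CPUE_i = BOAT_i / BOAT_max

where `BOAT_i` is the number of distinct vessels in cell *i* and `BOAT_max`
the busiest cell of the same period. Cells are binned on each environmental
variable; each bin's summed CPUE, scaled by the best bin, gives a suitability
index observation `SI_i = CPUE_i / CPUE_i,max ∈ [0, 1]`. The unimodal
environmental response is fitted by nonlinear least squares as a Gaussian
curve

    SI(x) = exp(−k (x − b)²),   k > 0,

with optimum `b` and curvature `k` (reported as the signed coefficient
`a = −k`). The composite habitat suitability index is the geometric mean of
the three single-factor indices,

    HSI = (SI_SST · SI_SSTA · SI_CHL)^(1/3),

graded into four equal bands (unsuitable < 0.25 ≤ generally suitable < 0.5 ≤
suitable < 0.75 ≤ most suitable). Model skill is the fraction of cells whose
predicted HSI lies strictly within 0.3 of the observed CPUE; six schemes
(0.1°/0.5°/1° × month/season) are rebuilt and ranked by the unweighted mean
of per-period accuracies. Scenario analysis shifts the seasonal baseline SST
by ±0.2/±0.5/±1 °C, repredicts HSI from the seasonal SST-only model and
accounts suitable (0.5 < HSI ≤ 0.75) and optimal (HSI > 0.75) areas on the
sphere.

## Worked example

```python
import squidhab as sq

grid = sq.GridSpec(110.0, 114.0, 6.0, 10.0, 0.1)
env = sq.generate_env_fields(grid, ["2016-03", "2016-06", "2016-09", "2016-12"], seed=42)
records = sq.generate_vessel_records(env, sq.TruthParams(), seed=42)

counts = sq.aggregate_vessels(records, grid.with_cell_size(0.5), sq.TemporalScale("season"))
cp = sq.cpue(counts["spring"])
sst = sq.aggregate_field(env["2016-03"]["sst"], grid.with_cell_size(0.5))

fit = sq.fit_seasonal_sst_hsi(cp, sst)
lo, hi = sq.si_range(fit, 0.6)
print(f"SI_SST = exp({fit.a:.3f} (SST - {fit.b:.3f})^2),  R2 = {fit.r_squared:.3f}")
print(f"optimal SST range (SI >= 0.6): {lo} to {hi} degC")

table = sq.scenario_suite(
    sq.ScenarioSpec(deltas=(0.0, 1.0, -1.0), models={"spring": fit}),
    {"spring": sst},
)
print(table[table["habitat_class"] == "suitable_or_better"].to_string(index=False))
```

prints

```
SI_SST = exp(-16.737 (SST - 28.508)^2),  R2 = 0.883
optimal SST range (SI >= 0.6): 28.33 to 28.68 degC
season  delta_degC      habitat_class     area_km2  area_ratio_pct  area_change_pct
spring         0.0 suitable_or_better 94872.640570           48.44              NaN
spring         1.0 suitable_or_better     0.000000            0.00          -100.00
spring        -1.0 suitable_or_better  6142.355072            3.14           -93.53
```

The fitted spring response peaks at 28.5 °C with a narrow optimal window
(SI ≥ 0.6 spans only ~0.35 °C here because the fitted curvature is large);
under a uniform +1 °C shift the whole region falls outside the suitable band
(HSI > 0.5) and the suitable area collapses to zero — the same narrow-niche
mechanism that makes tropical squid habitat sensitive to small SST anomalies.

The same pipeline is scriptable from the shell via the `squidhab` command
(`simulate`, `grid`, `cpue`, `fit-si`, `predict`, `validate`,
`compare-schemes`, `scenario`); see `squidhab --help`.

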