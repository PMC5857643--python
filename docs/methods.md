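# Methods

This note records the models implemented in `atsplan`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Stoichiometric accounting

Biomass is treated as a single reference molecule. The default,
C₁₀₆H₂₆₃O₁₁₀N₁₆P₁, is the classical Redfield-type organic-matter
composition; with standard atomic masses (C 12.011, H 1.008, O 15.999,
N 14.007, P 30.974) its mass fractions are R_C = 0.3583, R_N = 0.0631,
R_P = 0.00872 — i.e. 36%, 6.3% and 0.87% at two significant figures —
and R_PN = R_P/R_N = 0.1382. Any composition can be substituted; mass
fractions always sum to 1 by construction.

**Limitation labels.** A cell's excess-P to excess-N mass ratio GC_PN is
compared with R_PN: GC_PN > R_PN ⇒ `P_limited`, GC_PN ≤ R_PN ⇒
`N_limited`. Note the label names the *abundant* nutrient relative to
biomass stoichiometry, which is inverted relative to the usual Liebig
sense; we keep the convention because the ranking and sizing math only
needs a consistent dichotomy. Degenerate cases: both usable excesses
absent (≤ 0 or missing) ⇒ `none`; excess_N = 0 with excess_P > 0 ⇒
`P_limited`, the continuous N → 0⁺ limit of the rule.

**Biomass sizing.** The default `complete` policy takes
B = max(excess_N/R_N, excess_P/R_P) over positive, present excesses.
Rationale: harvesting B tonnes removes B·R_N of N and B·R_P of P, so the
max is the *least* biomass that recycles both nutrients entirely; any
per-label single-nutrient rule leaves part of one excess in place. The
literal per-label rule (`nonlimiting`: recycle P in N-limited cells, N in
P-limited cells) and fixed single-nutrient sizing (`N`, `P`) are provided
as options. Negative P (a deficit) contributes nothing to sizing —
deficits are not transferable between cells — but is preserved in the
data for reporting.

Units: nutrient excesses in kg per cell per year; biomass in metric
tonnes per year (1 t = 1000 kg).

## Area model

Areal productivity (t AFDW ha⁻¹ yr⁻¹) is linear in |latitude|:
p(φ) = p₀ + (p₄₀ − p₀)/40 · |φ|, with anchors p₀ = 91 and p₄₀ = 55 by
default. Hemisphere symmetry is hard-coded; longitude, climate and cloud
cover are deliberately ignored (the model is a planning envelope, not a
yield forecast). With the default anchors p stays positive to the poles
(p(90°) = 10); a guard raises if a user-supplied model goes nonpositive
inside the requested domain rather than silently clamping.

Required area is B/p(φ). Cell footprints use the spherical-zone closed
form A = R²·Δλ·(sin φ_N − sin φ_S) with R = 6371 km, exact on the
sphere, so a global tiling reproduces 4πR² to rounding error. The
per-cell ratio of cultivation area to cell area is reported; ratios above
a configurable threshold (default 1.0) trigger a logged warning, since a
cell demanding more floway than it has land signals either an extreme
hotspot or inconsistent inputs.

Grid resolution is a parameter (default 1° for speed; any cell size that
divides 360° evenly is accepted, including the ~5′ geometry of the real
global rasters).

## Basin ranking and concentration statistics

Cells are assigned to basins by containment of their center point —
consistent with summing "cells contained by" a basin and exactly
mass-conserving, unlike area-weighted splitting. Boundary points covered
by several polygons go to the lexicographically smallest basin id, making
the assignment a pure function of the geometry. Cells in no basin are
pooled as `unbasined` and reported, so the ranked column still sums to
the global total.

The ranking carries two percentage columns, since prioritisation tables
are read both ways: `share_pct` (and its cumulative sum) is the basin's
share of the summed ranked total, and `pct_of_basin_area` is the floway
area as a percentage of the basin's own footprint (computed from the
geodesic cell areas of its member cells when no footprint is given).

`concentration_stat(values, s)` returns the smallest fraction of items,
taken in descending order, whose sum reaches share s of the total — the
inverse Lorenz-curve lookup behind statements like "half the excess sits
in 7% of cells". `mass_share_bins` labels items `top10`/`next40`/
`bottom50` by cumulative mass, with boundary items going to the higher
bin; ties keep input order.

## Economic build-out simulation

A scenario is (CapEx $/ha, OpEx $/ha/yr, lifetime L years, growth rate
g = 0.10, growth years 100, horizon 200, unit productivity u, biomass
requirement). Spending follows S_t = S₀(1+g)^(t−1) for t ≤ 100 — growth
applied 99 times between year 1 and year 100, the convention consistent
with the published initial/final rate pairs — then stays at S₁₀₀.

Each year, in order: cohorts aged L retire; OpEx is paid on the surviving
area; the remaining budget buys new area at CapEx per hectare (the new
cohort operates, and produces biomass u·area, from its build year). The
allocation order is a modelling contract of this package, chosen as the
simplest rule under which OpEx + CapEx
outlays exactly exhaust each year's gross spending — a gross-expense
ledger with no hidden reserve. If the OpEx
obligation alone exceeds the budget, the newest cohorts are decommissioned
(partially if needed) until the survivors are affordable, with a logged
warning.

**Calibration.** S₀ is the least value (geometric bisection, relative
tolerance 10⁻⁶, bracket [1, 10¹⁵] $/yr with geometric expansion) such
that the minimum biomass over years 100–200 meets the requirement. The
binding years are the troughs of the "ringing", so a calibrated programme
overshoots the requirement at the peaks and its final spending rate
exceeds the closed-form steady-state plateau
`area · (OpEx + CapEx/L)`. This is why the simulated final rates come
out above the plateau figures, and the printed initial rates are best
interpreted as (final rate)/(1.1⁹⁹).

**Ringing.** Exponential build-up plus synchronized L-year retirement
makes post-completion biomass oscillate. The oscillation is *not* exactly
period-L: linearising the constant-budget phase gives the recurrence
n_t = −(OpEx/CapEx)·Σ_{j=t−L+1}^{t−1} n_j for the new-build perturbation,
whose dominant characteristic root is complex with period ≈ 1.25–1.3 L
under the published cost ratios (≈ 26 yr for L = 20 at OpEx/CapEx = 0.07).
The test suite verifies the simulated spectrum against this
characteristic-root prediction rather than against L itself.

**Presets.** Cost parameters: CapEx 2.5 × 10⁵ (best) / 1.0 × 10⁶ (worst)
$/ha; OpEx 3.3 × 10⁴ / 7.0 × 10⁴ $/ha/yr; lifetimes 40 / 20 yr. Two
lifetime pairings are runnable, since cost level and floway longevity can
plausibly correlate either way: the default pairs the worst case (high
costs) with 20-yr floways — the conservative combination whose closed-form
plateau is the upper-bound expense the package reports — and the
alternative (`proportional`) pairs low CapEx with 20 yr and high CapEx with
40 yr. Scenario-endpoint figures quoted in the cost literature are
retained as preset metadata only; the simulator never reads them. The
biomass requirement is
1.2 × 10⁹ t/yr for N/P recycling and 2.2 × 10¹⁰ t/yr for net
anthropogenic carbon; unit productivity defaults to the global
requirement divided by the global area requirement
(1.2 × 10⁹ / 1.9 × 10⁷ ≈ 63 t ha⁻¹ yr⁻¹), since the economic model is
aspatial. When the pipeline runs end-to-end it instead uses the totals it
just computed.

**Helpers.** `steady_state_expense` is the closed-form plateau above.
`fuel_power` converts a biomass flow to watts at 13.2 MJ/kg AFDW — the
fuel value of the carbohydrate and protein content, back-calculated so
1.2 × 10⁹ t/yr ↔ 5.0 × 10¹¹ W since the primary sources give no single
factor — averaged over a Julian year (3.1557 × 10⁷ s). Years are
integers; there is no discounting, inflation or revenue modelling. All
currency is 2018 US dollars.

## Synthetic worlds

The generator emulates the statistical structure of real excess-nutrient
rasters: nonnegative N, P of either sign, missing-data lacunae in
contiguous blobs, heavy-tailed magnitudes, spatially clustered hotspots,
and a basin partition. Mechanism: white noise → Gaussian smoothing
(wrap in longitude, clamp at the poles; correlation length 3 cells by
default) → re-standardise → exponentiate, giving a correlated lognormal
field. Missing cells and P-deficit cells come from thresholding further
smoothed fields at the configured quantiles (defaults 10% each), so both
form blobs rather than salt-and-pepper noise.

Default magnitudes: σ = 1.5 for both nutrients, calibrated through the
i.i.d. lognormal top-share relation — the fraction of cells holding half
the mass is 1 − Φ(σ), and 1 − Φ(1.5) = 6.7%, the concentration regime
observed in real rasters (~7% of cells hold half the excess). μ_N = 10.9
and μ_P = 8.6 (log kg/cell/yr) then set global totals of order 10⁷ t N
and 10⁶ t P on the default 1° grid via exp(μ + σ²/2) per cell. Spatial
clustering makes the per-seed concentration statistic noisier than the
i.i.d. value (correlated extremes arrive in blobs and usually *lower*
it), so ensemble tests check the median across seeds.

What the generator does **not** emulate: crop maps, fertilizer-application
processes, any real geography (basin shapes are planar Voronoi cells in
degree space), the N–P spatial correlation of real agriculture, or the
real rasters' ~5′ resolution (supported, but defaults are 1° for speed).
Passing tests therefore demonstrate correctness of the accounting,
geometry, ranking and economics on fields with realistic *statistics*,
not agreement with any real dataset's values.

A hand-set 10×10 fixture (4 missing cells, 6 P-deficit cells, two
rectangular basins, documented totals) is shipped in source form and
drives byte-exact golden-file regression of the whole pipeline.

## Numerical conventions and problem sizes

Coordinates are cell centers, latitude positive north, longitude in
[−180, 180). CSV output uses `%.10g` floats so repeated runs are
byte-identical. Randomness flows from a single integer seed through
`numpy.random.default_rng`; no time- or platform-dependent state is used.
Test and acceptance runs use desk-scale problems — 10×10 to 250×400 cell
grids, 200-year economic horizons, 20-seed ensembles — chosen so the full
suite completes in seconds while still exercising the heavy-tailed regime
the statistics need.

## Known limitations

- The limitation-label convention is inverted relative to Liebig usage
  (see above); downstream code treats labels as an opaque dichotomy.
- The productivity model ignores climate, seasonality and water
  availability along latitude lines; it is an upper-envelope planning
  device.
- Cell-center basin assignment misattributes straddling boundary cells
  entirely to one basin; at coarse resolutions this can visibly shift
  small basins' totals.
- The economic model is aspatial (one productivity, one CapEx/OpEx level
  globally) and models gross expense only — no revenue from biomass, no
  discounting.
- GeoTIFF input is not supported; rasters must be NetCDF with geographic
  lat/lon coordinates (a deliberate scope choice to keep the I/O stack
  small).
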