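# atsplan

Planning toolkit for large-scale recycling of excess agricultural nutrients
with algal turf scrubbing (ATS) — open-field cultivation of attached algal
polycultures on inclined floways.

Agricultural nitrogen and phosphorus that crops do not take up ends up in
fresh and coastal waters, driving algal blooms and pushing the global N and
P biogeochemical cycles past safe limits. Because algal biomass fixes N, P
and C in near-constant proportions, one can ask a precise planning
question: *how much algal cultivation, where, and at what cost, would it
take to recycle the excess completely?* `atsplan` answers it as a tested
pipeline:

1. **Stoichiometric sizing** — biomass mass fractions are derived from a
   reference elemental composition (default C₁₀₆H₂₆₃O₁₁₀N₁₆P₁, the
   classical Redfield-type organic matter), giving
   R_C ≈ 0.36, R_N ≈ 0.063, R_P ≈ 0.0087 and the P:N mass ratio
   R_PN = R_P/R_N ≈ 0.138. Each grid cell's P:N excess ratio
   GC_PN = excess_P/excess_N is compared with R_PN (cells with
   GC_PN > R_PN are labelled P-limited, otherwise N-limited), and the
   biomass required to recycle the cell's excesses is
   B = max(excess_N/R_N, excess_P/R_P) — the only sizing that removes
   *both* nutrients completely. The literal per-label rule and
   single-nutrient sizing are available as alternative policies.
2. **Area model** — areal productivity is linear in absolute latitude,
   anchored at 91 t ha⁻¹ yr⁻¹ (ash-free dry weight) at the equator and
   55 t ha⁻¹ yr⁻¹ at 40°; required area is B divided by the local
   productivity. Grid cells are spherical trapezoids, so area fractions
   (floway vs land) are exact on the sphere.
3. **Basin ranking** — cell areas are summed over basin polygons
   (cell-center containment), ranked, and summarised with Lorenz-style
   concentration statistics (e.g. the fraction of cells holding half the
   total excess) and 10%/40%/50% mass-share bins.
4. **Economics** — a 200-year cohort simulation: gross spending grows 10%
   per year for 100 years then holds constant; each year pays operating
   cost on surviving floway area and spends the remainder on new area,
   which retires after the facility lifetime. The initial spending rate
   is calibrated by bisection so the post-completion minimum biomass never
   falls below the recycling requirement. Closed-form helpers give the
   steady-state plateau expense, the fuel value of the biomass flow, and
   headline percentage comparisons.
5. **Synthetic worlds** — a seeded generator produces nutrient grids with
   the statistical structure real rasters have (nonnegative N, signed P,
   blob-shaped missing-data lacunae, heavy tails calibrated so ~7% of
   cells hold half the mass, spatial clustering) plus Voronoi basin
   partitions, so everything is testable without any download.

## Worked example

```python
from atsplan import (MassRatios, ProductivityModel, required_biomass, required_area,
                     classify_limitation, scenario_preset, calibrate_initial_spending,
                     simulate, steady_state_expense, fuel_power, percent_of)

ratios = MassRatios.from_composition()
print(f"R_C={ratios.r_c:.4f}  R_N={ratios.r_n:.4f}  R_P={ratios.r_p:.5f}  R_PN={ratios.r_pn:.4f}")

label = classify_limitation(120_000.0, 9_000.0, ratios.r_pn)   # kg/yr of excess N, P
b, sizing = required_biomass(120_000.0, 9_000.0, ratios)
area = required_area(b, 35.0, ProductivityModel())
print(f"limitation={label}  biomass={b:.1f} t/yr (sized by {sizing})  area={area:.1f} ha at 35N")

sc = scenario_preset("worst")            # high CapEx/OpEx, 20-year floways
s0 = calibrate_initial_spending(sc)
traj = simulate(sc, s0)
print(f"worst case: S0=${s0:.3g}/yr, final rate ${traj['spending'].iloc[-1]:.3g}/yr")
print(f"steady-state plateau for 1.9e7 ha: ${steady_state_expense(1.9e7, 1e6, 7e4, 20):.3g}/yr")
print(f"fuel value of 1.2e9 t/yr: {fuel_power(1.2e9):.3g} W "
      f"({percent_of(fuel_power(1.2e9), 1.8e13):.2g}% of primary energy)")
```

prints

```
R_C=0.3583  R_N=0.0631  R_P=0.00872  R_PN=0.1382
limitation=N_limited  biomass=1902.6 t/yr (sized by N)  area=32.0 ha at 35N
worst case: S0=$2.57e+08/yr, final rate $3.22e+12/yr
steady-state plateau for 1.9e7 ha: $2.28e+12/yr
fuel value of 1.2e9 t/yr: 5.02e+11 W (2.8% of primary energy)
```

Reading it: a cell with 120 t of excess N and 9 t of excess P per year is
N-limited (GC_PN = 0.075 < 0.138); recycling both nutrients takes ~1,900 t
of algal biomass per year, i.e. ~32 ha of floway at the 59.5 t ha⁻¹ yr⁻¹
productivity of 35° latitude. Globally, sustaining a completed worst-case
build-out of 1.9 × 10⁷ ha costs $2.28 × 10¹² per year in closed form; the
dynamic simulation needs a somewhat higher final spending rate because the
calibration must cover the troughs of the cohort-retirement "ringing".
The biomass flow embodies ~5 × 10¹¹ W of fuel value, 2.8% of global
primary energy.

The same pipeline runs from a shell:

```sh
atsplan all --source synthetic --seed 42 --outdir out/       # full bundle
atsplan all --source fixture --outdir out_fx/                # shipped 10x10 grid
atsplan econ --case best                                     # economics only
```

writing per-cell requirement and area tables, a basin ranking CSV, a
concentration/binning summary, the year-by-year economic trajectory and a
manifest that reproduces the run bit-for-bit.

## Layout

- `atsplan.nutrients` — compositions, mass ratios, limitation, biomass sizing
- `atsplan.area` — productivity model, required area, spherical cell geometry
- `atsplan.basins` — assignment, ranking, concentration stats, mass-share bins
- `atsplan.economics` — cohort simulator, calibration, closed-form helpers
- `atsplan.synth` — seeded synthetic worlds and the shipped regression fixture
- `atsplan.io`, `atsplan.pipeline`, `atsplan.cli` — formats, orchestration, CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
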