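# Methods

This note documents the models and procedures implemented in
`mangroveprio`, the choices made where the design was genuinely open,
and what the synthetic seascape does and does not emulate.

## The planning problem

Reserve selection is formulated as budget-constrained minimisation of
the weighted **proportional** shortfall

min Σ_f (w_f / t_f) · max(0, t_f − Σ_i a_fi x_i)   s.t.   Σ_i c_i x_i ≤ B,

with binary decisions x_i per planning unit, amounts a_fi, targets t_f,
weights w_f, unit costs c_i equal to mangrove area (km²), and budget B
expressed as a fraction of total mangrove area. The proportional form
(dividing each shortfall by its target) makes features measured in
different units — km² of a species' habitat versus rescaled service
points — commensurable in one objective; an absolute-shortfall form
would let large-area features dominate. Locked-in units (existing
protected areas at ≥50% coverage) enter as fixed x_i = 1. Units with no
mangrove are excluded from the problem entirely: they have zero cost
and zero amounts and would otherwise be selected arbitrarily.

Three solvers share this objective:

* `solve_exact` — a mixed-integer programme with auxiliary shortfall
  variables s_f, solved by HiGHS through `scipy.optimize.milp` at a
  relative optimality gap of 10⁻⁴ (0.01%) by default. If a time limit
  is set and reached, the best incumbent is returned with its reported
  gap.
* `solve_greedy` — adds, from the locked set upward, the affordable
  unit with the largest objective decrease per unit cost (ties: larger
  raw decrease, then lower unit id). A fallback and a speed option for
  large grids; its objective can only be ≥ the exact one.
* `brute_force` — exhaustive enumeration for ≤20 units; the test
  oracle. Ties among optima resolve to the cheaper selection, then the
  lexicographically smallest id tuple.

Determinism: all tie-breaks throughout the package resolve toward the
lower unit id, so repeated runs with one seed are bit-identical.

## Nested priority ranks

Ranks come from re-solving the same problem over a strictly increasing
grid of budget fractions (default 5%-of-area steps in the pipeline;
1% steps are a configuration away) with every unit selected at an
earlier step locked in. This *enforces* nestedness — each solution
contains all smaller-budget solutions — and defines a unit's rank as
the first budget step at which it is selected; initially locked-in
(already protected) units carry rank 0. Independent solves per budget
need not nest, which is why sequential lock-in is the mechanism here.
At a terminal step with a budget equal to total cost the solution is
defined as the entire seascape: at full budget protecting more costs
nothing, and this guarantees rank maps cover every unit, accumulation
curves end at 100% of every service, and all targets are met at
budget 1.0 (every target satisfies t_f ≤ Σ_i a_fi by construction).
A consequence of sequential lock-in: when the initially locked estate
exhausts the first budget step, free units begin entering only at the
first step with residual room.

## Conservation features and targets

Each species' per-unit mangrove area is split by the unit's predominant
biophysical typology and marine province; every unit carries exactly
one label of each, so sub-feature totals partition the species' range
area exactly (asserted to 1e-9 relative). Sub-features below 1e-6 km²
are dropped as degenerate. The target fraction is interpolated from the
**species'** global range area and applied to each sub-feature's own
total: the interpolation rule is defined on the range of the species,
and per-sub-feature interpolation would give a species' tiny peripheral
slices 100% targets regardless of how widespread the species is. The
alternative (`interpolate_on="subfeature"`) is implemented behind a
switch for comparison. The rule itself: 100% at ≤10,000 km², 10% at
≥250,000 km², log₁₀-linear between; it is continuous, non-increasing,
and exactly 55% at the geometric mean 50,000 km².

## Ecosystem-service processing

* **Nearest-neighbour fill**: units missing a value take the value of
  the nearest unit with data (centroid Euclidean distance in the planar
  frame; ties to the lower unit id). Idempotent on complete layers.
* **Point allocation** (flood-protected people and property): each
  source value is divided by the total mangrove area of the group of
  units sharing it after filling, giving a per-km² rate, then
  re-multiplied by each unit's mangrove area. Group sums reproduce the
  source value exactly (1e-9 relative); groups with zero mangrove area
  are dropped with a warning.
* **Densities** (carbon, fishing): zonal mean of samples per unit (one
  value per unit in synthetic mode), then stock = density × mangrove
  area. Above-ground and soil carbon densities are summed before the
  stock conversion. Fishing intensity is likewise converted from
  fisher days km⁻² yr⁻¹ to a per-unit total so that optimisation
  amounts and reported totals share one definition.
* **Rescaling**: per-unit totals are mapped linearly to [0, 1000]
  (min→0, max→1000). Min–max is used rather than divide-by-max because
  the stated range is 0–1000 and a ratio scale would not generally
  reach 0. Constant layers map to all-zero with a warning and are
  excluded from the objective (no signal). Rescaling happens **after**
  density→stock conversion, i.e. on the final per-unit totals. Raw
  native-unit totals are retained alongside for all reporting.

Service features enter the objective with target = 100% of the rescaled
total and weight 1 by default; the weighted scenario raises all service
weights (the pipeline default is 100; 10 and 1000 are conventional
alternatives) to favour service-rich units over purely biodiverse ones.
Services are treated linearly in the objective (no caps).

## Evaluation

* **Representation**: amounts held by a selection per feature; a target
  counts as met at ≥ t_f·(1−1e-9).
* **Accumulation curves**: cumulative raw service totals and percent of
  the global total over the budget grid, walking the nested ranks
  (rank-0 units are in every selection); optionally percent of targets
  met per step. Curves are non-decreasing and end at 100%.
* **Gap analysis**: coverage percentages are mangrove-area-weighted
  (share of total mangrove area inside protected units), not unit
  counts — matching how global coverage statistics are quoted. Class
  means (strict PA / other PA / prioritised-not-PA) use raw per-unit
  service values.
* **Cohen's κ**: computed on unweighted unit membership by default
  (κ = (p_o − p_e)/(1 − p_e), p_e from the selection marginals); an
  area-weighted variant is available via `area_by_unit`. When p_e = 1
  (both marginals degenerate) κ is 1 for perfect agreement and NaN
  otherwise.

## The synthetic seascape

The generator emulates the statistical structure of the global inputs
so the pipeline is testable without downloads:

* hexagonal planning units every 20 km along a straight abstract
  coastline in a planar equal-area frame (no CRS machinery; real-data
  mode treats coordinates as planar);
* per-unit mangrove area lognormal (median 1,000 km², σ_log = 0.5).
  This is deliberately far above the real global mean (~15 km² per
  20-km unit): species range areas here are realised sums of per-unit
  mangrove area, and spanning the target-rule thresholds
  (<10,000 to >250,000 km²) within a few hundred units requires
  correspondingly large units. The seascape is a scaled model system,
  not a miniature Earth;
* species ranges as contiguous runs of units: a range-area spectrum is
  drawn log-uniformly between configurable bounds
  (default 2,000–350,000 km²) with the smallest and largest species
  anchored at the bounds so the spectrum spans the target thresholds
  for every seed; the run accumulates whole units (partial last unit)
  until it realises its drawn area, so realised range area equals the
  drawn value whenever the strip is long enough;
* typologies in spatially clumped runs (mean 5 units); provinces and
  zones (country stand-ins) as contiguous blocks;
* service layers per unit: people and property lognormal with
  σ_log = 2.3 (max/min ratio > 10³ over ≥100 units), carbon density
  normal around 0.096 Tg C km⁻² (σ = 0.006, floor 0.06 — max/min well
  under one order of magnitude), fishing intensity lognormal with
  σ_log = 1. A configurable 30% of units per layer are left missing to
  exercise nearest-neighbour filling. An optional smoothing radius can
  impose spatial autocorrelation; it defaults to off because no
  empirical value is available to match;
* protection fractions drawn so that ≈13.5% of units have ≥50% strict
  coverage and ≈43% have ≥50% coverage under any category, with
  any ≥ strict per unit;
* one root seed; each component (areas, zones, typologies, species,
  services, protection, hotspots) draws from a child generator at a
  fixed documented offset, so adding a component never perturbs the
  others, and a fixed seed yields byte-identical output.

What the seascape does **not** emulate: real coastline geometry,
spatial covariance between species richness and service value (services
are independent of biodiversity here, whereas in reality they co-occur),
country-scale heterogeneity, and any loss/deforestation dynamics.
Passing tests therefore demonstrate the correctness and qualitative
behaviour of the *method* — target interpolation, optimality,
nestedness, conservation of allocated totals, curve shapes — not
real-world magnitudes of coverage or service capture.

`plant_hotspots` multiplies a named service at k random units-with-data
by a factor and records the ids, enabling parameter-recovery tests: with
5 hotspots at 100× and the planted service weighted 1000, planted units
should surface in the top-decile ranks. The recovery experiment plants
on the moderately skewed fishing layer: on the heavy-tailed layers
(σ_log = 2.3) the natural extremes are the same order as a 100×
implant, so recovery there would measure the layer's own tail rather
than the implanted signal. Recovery is not perfect by construction — a
plant on a unit whose pre-plant draw sits near the distribution floor
remains low-value after rescaling — and sits at the 95% boundary under
the default conditions.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use scaled-down instances
chosen as the package's own working sizes: 200-unit / 20-species
seascapes with 10%-of-area budget steps for end-to-end runs, 30–120
units for property sweeps, ≤12 units for enumeration oracles. The
full-scale configuration (9,111 units, 65 species, 1% steps) is
expressible through the same configuration objects. Feasibility
tolerances are 1e-9 relative throughout; budgets and targets compare
with a (1+1e-9) slack to absorb float accumulation; the MILP gap
default is 10⁻⁴. Degenerate inputs (constant service layers, empty
species, zero-area sharing groups, locked cost exceeding a budget) are
either warned about and neutralised or rejected with errors naming the
offending field, as documented per function.

## Known limitations

* GIS I/O is GeoJSON only; GeoPackage is not read or written.
* Real-data ingestion expects pre-intersected per-unit tables; the
  25-m raster intersection of cover with ranges is upstream of this
  package, and the upstream service models (flood propagation, biomass
  allometry, soil-carbon estimation, fishing-effort modelling) are
  consumed as values, never recomputed, so their caveats are inherited.
* Exact nested ranking at fine (1%) budget grids on thousands of units
  is MILP-heavy; the greedy solver is the practical choice there.
* No connectivity or boundary-length penalties are implemented.
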