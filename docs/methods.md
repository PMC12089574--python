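# Methods

This note records the model semantics, the numerical choices made where
published descriptions of the CLIMEX family of models are silent, the
design of the synthetic data, and the known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The climatic niche engine

### Model year and weekly interpolation

The engine works on a 52-week model year of 364 days divided into 12
equal months (364/12 days each). Monthly climatologies are converted to
weekly series by

* **periodic cosine interpolation** between month midpoints for point
  variables (Tmin, Tmax, RH) — smooth, constant-preserving, and free of
  overshoot beyond neighbouring monthly values (for an annual sinusoid of
  amplitude A the week-midpoint error is below 0.06·A);
* **day-overlap redistribution** for precipitation totals — each week
  receives every month's total in proportion to their day overlap, so the
  annual total is conserved to machine precision.

### Growth indices

Weekly driver temperature for TI is Tavg = (Tmin + Tmax)/2. TI is the
trapezoid 0 at/below DV0 = 9.4 °C and at/above DV3 = 39.5 °C, 1 on
[DV1, DV2] = [26, 30] °C. MI is the trapezoid over the soil-moisture
index with SM0 = 0.1, SM1 = 0.65, SM2 = 1.5, SM3 = 2. GI_A =
100 · Σ(TI·MI)/52. The annual degree-day sum is Σ max(0, Tavg − DV0) · 7,
compared against PDD = 392 °C·days, the minimum for one generation
(egg-to-adult development needs ≈ 391.6 °C·days; the engine is
insensitive to the rounding).

### Soil-moisture bucket

A weekly bucket of capacity 100 mm: inflow is precipitation, outflow an
evapotranspiration demand k · max(0, Tavg) · (1 − RH/100) with k = 1 mm
per °C per week and RH the mean of the 09:00 and 15:00 values. k was
chosen so that a hot, dry cell (Tavg ≈ 30 °C, RH ≈ 30 %) drains a full
bucket within a few weeks while humid-tropical cells stay saturated.
The carried **storage** is clamped to [0, capacity]; the **index**
reported to MI and to the dry/wet stresses is the pre-runoff balance,
clipped to [0, 3]. A week whose inflow would overfill the bucket
therefore shows transient super-saturation (index > 1, up to 3) without
that excess persisting — this is what makes the SM2 = 1.5 / SM3 = 2
super-saturation thresholds meaningful while preventing every
persistently rainy cell from accumulating lethal wet stress (which would
wrongly zero EI across the humid tropics). Wet stress consequently
requires genuinely torrential weeks (inflow ≳ one full capacity above
demand on a full bucket).

The series is spun up over repeated annual cycles from half-full storage
until the weekly storage changes by < 1e−6 between cycles (cap 500
cycles; non-convergence raises, naming the cells). With clamped linear
dynamics convergence is geometric; a balanced budget (P = E every week)
is the one neutral case and legitimately holds its initial level.

### Stress accumulation

Each stress k has a threshold and a weekly rate (cold: Tmin below
TTCS = 9.4 °C at |THCS| = 0.003; heat: Tmax above TTHS = 39.5 °C at
0.005; dry: index below SMDS = 0.1 at 0.005; wet: index above SMWS = 2 at
0.01). The weekly increment is |rate| · deficit, expressed in percent.
The published accounts describe stress as accelerating with episode
length but give no formula; the engine multiplies each increment by the
elapsed-week count of its contiguous stress episode (a linear time ramp),
with episodes tracked across the year boundary (a split winter episode
accumulates exactly as an equivalent mid-year one). The ramp is a config
switch (`linear` | `flat`) so sensitivity can be tested. The annual sum
is clipped to [0, 100]; 100 is lethal. Under this scheme a permanently
cold cell (Tmin = 0 °C year-round) saturates cold stress, and a single
week 1 °C below threshold contributes 0.3 points.

### Integration, irrigation, classification

EI = GI_A · Π(1 − S_k/100), forced to 0 on lethal stress or DD < PDD, so
0 ≤ EI ≤ GI_A ≤ 100 by construction. The irrigation scenario applies
effective daily water max(rain, 2.5 mm/day) year-round on masked cells
("top-up" reading: rainfall already at or above 2.5 mm/day is unchanged;
an additive mode exists as a config option because the alternative
reading rain + 2.5 differs for 0 < rain < 2.5). Suitability classes are
upper-inclusive exactly as printed: unsuitable EI = 0, marginal
0 < EI ≤ 5, moderate 5 < EI ≤ 15, suitable 15 < EI ≤ 30, optimal EI > 30.

The engine targets the documented semantics of this model family, not
bit-compatibility with any proprietary binary; validation is through
invariants (monotonicities, rotation invariance of GI_A, EI ≤ GI_A) and
constructed climate profiles whose regime is known by design.

## Occurrence cleaning

The cascade order is fixed (missing/invalid coordinates → null island →
absent/fossil/living → centroid → capital → pre-1950 → default/high-
uncertainty coordinates → zoo/herbarium → ocean) and each record is
charged to the first filter that removes it, so report counts reconcile
exactly. Choices where no published value exists: the high-uncertainty
cutoff is 25 km (configurable); the duplicate key is rounded coordinates
at 4 decimal places (~11 m) plus year, keep-first with optional source
priority; known-bad default coordinates are a configurable blacklist; the
centroid/capital/zoo tests accept precomputed boolean columns or a
user-supplied gazetteer (no world gazetteer is bundled); the ocean test
uses a supplied land mask and retains records without coverage.
Unparseable rows are quarantined and counted, never silently dropped.
Geo-referencing of textual localities is out of scope.

## Migration analysis

Distances are great-circle (haversine, sphere R = 6371.0088 km) from each
transient record to the nearest hub cell centre; the hub is the raster-
native set of EI > 0 cell centres (polygonised hulls are display-only, to
avoid polygonisation artefacts in distances). Exclusion regions (e.g.
isolated oceanic areas whose records would imply implausible single
flights) are a configurable geometry list. Percentiles use linear
interpolation between order statistics (numpy's inclusive convention —
fixed and documented because no published convention exists); F(D) is the
right-continuous step value, PP = 1 − F(D) is therefore non-increasing in
D. Buffer zones are unions of geodesic circles around hub points at each
percentile radius, nested by construction. Region centroids are
area-weighted in a local equirectangular frame scaled by cos(latitude),
adequate at member-state extents; whether production-weighted centroids
or a restricted hub subset should be used instead is a config decision
left to the analyst.

## Economics

R̄ and OC̄ in the with-pest margin are the same panel means that enter
the baseline, so PP = 0 implies DEI = 0 exactly and
DEI = R̄ · PP · YL/100 holds as an algebraic identity (asserted to 1e−9).
Area scaling uses the multi-year mean cultivated area (year-specific
areas are a config option; the choice cannot be resolved from published
figures). The no-control scenario leaves operating costs unchanged;
control-cost hooks exist and default to zero. The scenario percentiles
are 2.25 / 50 / 97.5 (the 2.25 is kept exactly as printed, not
"corrected" to 2.5). Full precision is carried internally; €/ha are
rounded to integers and million € to one decimal only in the
presentation tables.

## Synthetic data

The default world is a 40 × 80 grid at 0.5°, latitudes 0–20°, with four
designed bands (per-band mean temperature, seasonal amplitude, rainfall
and humidity, plus seeded per-cell noise of 0.3 °C and 5 % rain):
tropical (warm/moist, built to give EI > 30), mediterranean (mild
winters — permanent with small cold-stress accumulation; its ten western
columns are a desert-rainfall, irrigation-masked stripe that is
unsuitable rainfed and suitable irrigated), continental (warm moist
summers, winters far below the cold-stress threshold — EI = 0 with
GI_A > 0), and polar (summers below DV0 — GI_A = 0). Band temperatures
step discontinuously at band edges; this is deliberate, so every cell of
a band realises its intended regime rather than straddling a boundary.
The grid size keeps a full engine run under a second.

The dispersal kernel is 0.7·Gamma(2, 150 km) + 0.3·Gamma(6, 200 km) —
right-skewed and bimodal like observed seasonal migration-distance
distributions; the parameters are configuration, not biological claims.
Occurrence records launch from the hub's northernmost front on bearings
within ±2° of due north, so the sampled kernel distance equals the
realized nearest-hub distance to within the bearing geometry error
(≤ 0.5 %); a wide bearing cone over a raster-cell hub cannot satisfy that
equality at small distances, which is why the cone is narrow by default.
Dirty records (an exact `round(fraction · n)` count) cycle through every
cleaning-filter category plus duplicates, with truth labels naming the
filter expected to remove each.

Synthetic state hub distances are drawn within (100, 700) km — inside
the synthetic world's transient reach (its continental band ends ≈750 km
from the hub edge), mirroring assessments in which every region at risk
lies within the maximal observed migration distance.

What the synthetic world does **not** emulate: real geography and
coastlines, inter-annual variability, orography, humidity seasonality,
spatially correlated noise, wind-assisted trajectories, and the absolute
values of any real climatology. Passing tests therefore demonstrate the
correctness and internal consistency of the machinery under known
conditions, not predictive skill on real climate or occurrence data.

## Known limitations

* The exact proprietary soil-moisture and stress-accumulation formulas
  are unpublished; the bucket scheme and the linear episode ramp are this
  package's own documented approximations, flagged by config switches.
* Native-range migration statistics (median and upper-percentile hub
  distances, island-exclusion counts) require the original compiled
  occurrence dataset and a 1995-centred global climatology; neither can
  be redistributed here, so the corresponding acceptance check reports
  its missing inputs rather than a number.
* Parameter fitting against occurrence data, future-climate scenarios,
  stress-interaction indices, trade-pathway dispersal and mechanistic
  spread simulation are out of scope.
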