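# Methods

## Scope and model

`forestcondition` implements an ecosystem condition account for forests in
the sense of the UN System of Environmental-Economic Accounting — Ecosystem
Accounting (SEEA EA). The account measures, for each forest ecosystem type
and accounting year, how similar the forest is to a natural reference
condition on a 0–1 scale, following the standard three-step scheme:

1. **Variables.** Seven condition variables on their native scales:
   vegetation water content (NDWI, −1..1), soil organic carbon (0..1,
   normalised), species richness of threatened forest birds (0..22),
   tree cover density (0..100%), productivity (NDVI, −1..1), forest
   connectivity (forest area density, 0..100%) and landscape naturalness
   (0..100%). The last two are computed internally from the land cover by
   moving-window analysis; the others are inputs (or, in synthetic scenes,
   generated fields).
2. **Indicators.** Each variable is rescaled per forest type with the
   clamped min-max transform `I = (V − V_L)/(V_H − V_L)`, where the lower
   level `V_L` is the minimum of the ambient distribution of the type and
   the upper level `V_H` is the maximum observed in reference sites.
   Values at or beyond the levels clamp to 0 and 1. Both levels are
   measured on the first accounting year (the reference year) and applied
   to all years.
3. **Index.** The condition index of a cell is the weighted sum
   `Σ_j w_j x_ij` with rank-derived weights summing to 1
   (defaults 0.08, 0.12, 0.22, 0.21, 0.13, 0.13, 0.11 for ndwi, soc,
   birds, trees, ndvi, fad, lm); the per-type index is the mean over the
   type's cells. When a variable is structurally absent for a type, its
   weight is redistributed proportionally over the remaining indicators;
   cell-sporadic data holes instead propagate to no-data, which keeps a
   clean distinction between "this type has no such data" and "this cell
   is broken".

Forest ecosystem types are the cross of four forest land-cover classes
(broad-leaved, coniferous, mixed, transitional woodland and shrub) with up
to eleven biogeographic regions — at most 44 types. Type identifiers are
`region_code*10 + class_code`, chosen for stability and readability.

## Reference sites

Upper levels come from primary-forest polygons merged with strictly
protected areas (IUCN Ia/Ib/II). A polygon qualifies when it contains at
least 7.5 ha of forest — the minimum treed area of a 25 ha minimum mapping
unit under a 30% canopy-cover delineation criterion — and its cumulative
tree-cover loss is at most 5% of that forest area. Forest, for this
purpose, is canopy cover strictly above 20% (20% is read as the
open-habitat limit; the comparison is configurable). Cell membership in a
polygon uses cell-center containment, which is deterministic and
resolution-consistent. The loss mask is the any-year union of annual loss
layers. Exactly 7.5 ha passes the area filter (only "below" is excluded)
and exactly 5% passes the loss filter; both boundaries are tested.

Regions without any admissible site borrow upper levels from a
climatically analogous region for the same forest class
(Arctic ← Alpine-Scandinavia; Black Sea, Steppic ← Pannonian by default).
If a fallback source is itself empty the level is left missing and the
type is pushed to the highest uncertainty class. A fallback can place
`V_H` below the type's own `V_L`; such rows are clipped to `V_H = V_L`
(the indicator is then 0 everywhere) and logged. Degenerate `V_H = V_L`
rescaling likewise returns 0 — an uninformative indicator reads as
degraded rather than silently as pristine.

An optional robust floor (percentile instead of absolute minimum) exists
for `V_L` but is off by default; the default reproduces the plain
ambient-minimum rule. Likewise `V_H` is an absolute maximum by default
with a percentile option.

## Landscape metrics

Forest area density (FAD) and naturalness both use a square moving window,
default 23 × 23 cells = 529 ha at 1-ha cells. Counting is done with an
integer summed-area table, so results are *exactly* equal to exhaustive
per-cell counting (this is asserted against a double-loop oracle in the
tests). At map edges the window shrinks to its in-bounds part by default —
this avoids artificially depressed densities along the border — with a
zero-padding mode available for strict emulation of fixed-denominator
tools. FAD percent is classified into six connectivity classes with edges
rare [0,10), patchy [10,40), transitional [40,60), dominant [60,90),
interior [90,100), intact {100}; the class edges are a convention (the
6-class scheme of common fragmentation toolboxes) and are configurable.
Naturalness reclassifies land cover into a 3-way
agriculture/natural/developed mosaic (all four forest classes count as
natural), takes the windowed natural proportion, and snaps it to the
nearest of twelve category labels [0, 5, 15, …, 95, 100]; ties round up.
The index uses FAD percent and the naturalness category value as the two
landscape variables.

## Bird richness model

Threatened-bird richness per survey cell is modelled with a quasi-Poisson
GLM (log link, Var = φ·μ), appropriate for over-dispersed counts. The
pipeline is: (1) drop survey cells whose *total* reported richness is
below 3 species (a proxy for sampling effort) and any excluded strata;
(2) greedily prune predictors from pairs with |Pearson r| > 0.7, keeping
the member more correlated with the response; (3) forward stepwise
selection in which candidates enter in descending |correlation with the
response|, each step fits the linear term and then its centered quadratic
companion, and a term is kept when its Wald p-value (at the Pearson-χ²
scale) is below 0.05 *and* it improves the deviance pseudo-R²
(1 − D_res/D_null) by more than 0.005. The search stops at the first
failing candidate by default (`scan_all=True` keeps scanning). The
0.005 improvement threshold and the 0.05 significance level are defaults
of this implementation; both are arguments. Quadratics are centered before
squaring purely for numerical conditioning — fitted means are unchanged.

Validation reports hold-out RMSE and observed-predicted correlation on a
70/30 split plus repeated k-fold cross-validation (10 folds; repeats are
configurable — full-scale analyses use 100, the test suite uses small
counts) in which the *selected* terms are refit per fold. Projection onto
grids applies the inverse link cellwise; dynamic predictors may differ by
year while climate grids are held constant, and a missing grid fails
loudly with the predictor's name.

## Change and significance

Change is reported in absolute index points × 100: an index moving from
0.648 to 0.682 is a change of +3.4. Relative change is available behind a
flag. Area shares of increasing/decreasing condition are computed over
cells with a defined index in both years, making them invariant to
surrounding non-forest. Per-type significance uses a two-sided
Mann-Whitney U test (normal approximation with tie correction) on random
cell samples thinned to a minimum pairwise distance (default: the window
size, 23 cells) to suppress spatial autocorrelation. The two years are
sampled independently by default; this makes the test correctly
calibrated under the null of no change — with identical grids a same-cell
comparison would be fully tied and the test degenerate. A same-cell mode
(`independent_samples=False`) is provided. When fewer cells than requested
survive thinning, all survivors are used and the row is flagged.

## Uncertainty classification

Each type receives four scores in 1..4: reference-site extent
(>100 km² AND >2% of the type's forest area → 1; one of the two → 2;
neither → 3; no sites → 4), environmental representativeness (mean
|z-score| of reference-site elevation, slope, temperature and rainfall
against the type's distribution, bins [0,0.3) → 1, [0.3,0.7) → 2,
[0.7,1.2) → 3, ≥1.2 → 4), and the share of forest whose class matches the
potential natural vegetation, over the whole type and over its reference
sites (>75 → 1, (50,75] → 2, (25,50] → 3, ≤25 → 4). Bin membership at the
printed boundaries is assigned to the worse (higher-uncertainty) side,
documented and configurable. z-scores use the type's population standard
deviation; absolute values are averaged by default (a signed mode exists).
The final level is the mean of the four scores rounded half away from
zero, so a tie (mean 2.5) resolves conservatively to 3.

## Sensitivity analysis

The per-type index depends on 21 parameters (V_L, V_H, w_j × 7
indicators). One-at-a-time: V_L is only increased by 10% (most lower
levels sit at a natural floor), V_H only decreased by 10%, and each
weight is increased by 10% with the others scaled by
`(1 − 1.1 w_k)/(1 − w_k)` — the unique renormalization preserving their
relative ratios. Perturbations are multiplicative, so zero-valued
parameters are fixed points. Each row recomputes rescaling and
aggregation with exactly one parameter changed and reports percentage
deviation from the nominal index (absolute deviation, flagged, when the
nominal index is 0). If a perturbation makes V_H < V_L the pair is
clipped and flagged. The weight-consensus identity — if all indicators
equal c, any valid weight vector gives index c — serves as the null check.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes,
not any real geography. Spatially autocorrelated fields are Gaussian-
smoothed white noise (sigma = the stated correlation range in cells) —
the simplest controllable correlation structure. Land cover is thresholded
from such a field (forest fraction 0.6 by default) and split into the four
forest classes by quantiles; regions are a nearest-seed tessellation of up
to 11 contiguous zones. Reference sites are the top 8% of a score that
mixes a random field with elevation, reproducing the real-world bias of
remnant natural forest toward high, cold terrain; the resulting blobs are
rasterized cells vectorized back to polygons, so polygon and raster are
consistent by construction. Polygons alternate primary/protected origin,
protected ones drawing IUCN categories mostly from the strict classes.
Condition variables get a configurable additive uplift inside reference
sites (defaults ≈10% of each native scale) and a second accounting year
via an independent drift field with a small positive default mean. Sparse
loss patches cover 2% of the forest by default. Grids are row-major with
cell (0,0) at top-left and 1-ha cells.

Bird tables draw 15 standardized predictors with mild cross-correlation
among land shares and simulate counts from a known log-linear truth
(intercept log 4; forest share 0.45, summer NDVI 0.30, temperature 0.35
with quadratic −0.20; dispersion 2) via a gamma–Poisson (NB1) mixture
whose variance is exactly φ·μ. Effect sizes and the cross-correlation
strength were chosen once so the generating terms are identifiable by the
stepwise procedure at n = 5000 — i.e., each active predictor's marginal
correlation exceeds that induced on any inactive one. An optional mode
appends near-collinear longitude/latitude columns (17 predictors) to
exercise the pruning step.

What the generator does *not* emulate: sensor noise, cloud masks,
reprojection artefacts, land-cover change between years, realistic
variograms, or the actual European magnitudes of any variable. Passing
tests therefore demonstrate correctness of the accounting machinery and
calibration of its statistics under known truth, not agreement with any
real-world dataset.

## Numerical choices and problem sizes

Window counting is integer-exact; index aggregation is checked against an
independent double-loop recomputation to 1e-10 on 100 seeded scenes.
Weights must sum to 1 within 1e-9 at construction. The demo and
verification runs use desk-scale problems chosen to exercise every code
path: 96×96 scenes for the end-to-end account, 24×24 scenes for the
oracle sweep, n = 5000 observations × 50 replicates for stepwise
recovery, 100–200 seeds for the rank-test calibration. All randomness
flows from explicit integer seeds; identical configuration gives
bit-identical scenes and byte-identical CSV outputs.

## Known limitations

- No CRS handling: all inputs must already be co-registered on one grid;
  rasters are plain single-band TIFFs on an abstract metric grid.
- Reference levels are static (measured once on the reference year);
  dynamic or periodically updated reference conditions are out of scope.
- The Mann-Whitney test treats the two years as independent samples; a
  paired design would be more powerful where cellwise pairing is
  meaningful.
- The uncertainty scheme is ordinal and semi-quantitative by design; the
  four criteria are equally weighted in the final rounding.
- Only one-at-a-time sensitivity is provided (no variance-based indices).
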