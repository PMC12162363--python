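# Methods

This note documents the models behind each pipeline stage, the parameter
defaults and why they were chosen, what the synthetic landscape does and
does not emulate, and the numerical conventions that make results
reproducible.

## Grid model and geometry

All gridded quantities are single-band, north-up, row-major grids with an
affine placement and a CRS (`GridRaster`). Cell (0,0) is the northwest
corner; coordinates refer to cell centers; pixel extents are half-open.
Rasters entering a joint computation must share shape, transform and CRS
exactly — alignment is *checked*, never repaired by silent resampling, and
a mismatch raises immediately. Nodata is carried as NaN and propagates:
any stage's output is nodata wherever any input is.

Areas on projected (equal-area, metre) grids are |Δx·Δy|/10⁶ km² per cell.
On geographic grids each row's cells get the spherical quadrangle area
R²·Δλ·(sin φ_n − sin φ_s) on the authalic sphere (R = 6371.0072 km); the
error against ellipsoidal integration is far below any reported precision.
Great-circle distances use the haversine formula on the same sphere.

GeoTIFF I/O is implemented directly over tifffile with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA); round-trips are bit-exact for finite values. Vector layers
are shapely geometries in GeoJSON; invalid polygons are repaired on load.

## Synthetic landscape

The generator emulates the statistical structure a regional diversity
analysis assumes, with full ground truth:

- **Covariates** are stationary Gaussian random fields synthesized
  spectrally (FFT of white noise filtered by the spectrum of a Gaussian
  correlation kernel, default length 10 cells), standardized to mean 0,
  variance 1. Fields are mutually independent draws.
- **Species truth**: suitability_i = logistic(αᵢ + Σₖ βᵢₖ·cₖ) with
  coefficients drawn per species (β ~ N(0, 2²)); the true range is the
  top-q cells of suitability, where q is a log-normal draw (default
  ln-mean 4.5, ln-sd 1.3, clipped to [1, 30% of cells]) — a long-tailed
  range-size distribution in which many species later yield < 4 records.
- **Occurrences**: per species 1 + Poisson(range_cells × 0.08) records,
  drawn from true-range cells with probability ∝ (1−b) + b·effort(cell)
  where effort is a smooth field and b = 0.5 (moderate survey bias); 5% of
  rows are duplicated verbatim and 10% are flagged vague with coordinates
  jittered inside a 5-km radius, exercising deduplication and buffering.
- **Reserves**: random discs accumulated until their union is ≈ 6% of the
  landscape (the study region's reserve share).
- **Sub-basins**: a two-level nested Voronoi partition (12 coarse, 60 fine
  seeds by default); each fine seed is owned by the coarse cell containing
  it and cells pick the nearest owned fine seed, so level-2 basins nest
  exactly inside level-1, as nested hydrological basin products do.
- **Footprint**: a [0,1] built-environment layer constructed to correlate
  at −0.6 with the first covariate (human pressure anticorrelated with the
  richness driver).

The landscape lives in a projected equal-area CRS with metre coordinates
(1-km cells), so buffer areas and distances are exact. One seed fixes every
artifact.

What it does *not* emulate: realistic climate surfaces and their mutual
correlation structure, mechanistic dispersal limits, temporal turnover,
taxonomic error, and the real geometry of river networks. Passing tests
therefore demonstrate that the *algorithms* recover known structure under
the stated statistical assumptions — not that any particular real-world
map is correct.

## Occurrence cleaning

Vague records carry a locality point and a vagueness radius; buffering
turns them into discs usable for sub-basin intersection (their disc hulls
also enter MCP construction). Thinning applies, per species: exact
duplicate removal (keep first by record id), one record per 10 × 10 km
pixel, then greedy radius thinning visiting records by descending local
density then record id, keeping a record iff it is ≥ 10 km from everything
already kept. The order is a package convention chosen for determinism;
thinning is idempotent and every removal is logged with exactly one reason
(duplicate / within-thinning-radius / outlier). Outlier removal (records
farther than 500 km from the species' coordinate centroid) is available
but off by default, since no principled rule exists for data this sparse.

## Range construction

**Screening.** Covariates are screened on the landscape: while any pair has
|r| ≥ 0.9 the member of the worst pair with higher mean |r| is dropped,
then the highest-VIF variable is dropped until all VIF < 5. Survivors with
zero permutation importance in a preliminary fit are also dropped.

**Suitability model.** A ridge-penalized logistic regression on
standardized linear + quadratic covariate features, fit presence vs
background (min(10 000, 10 × presences) cells drawn uniformly from the
modelling region). This preserves the structure of low-sample
maximum-entropy modelling — a smooth suitability surface from
presence-background contrast — with one penalty hyperparameter chosen by
cross-validated AUC over a small grid. Cross-validation uses k = 10 folds
(fewer when presences < 10). Externally produced suitability rasters can
be substituted at the binarization step.

**Binarization.** Models must clear mean CV AUC > 0.75. Suitability is
averaged over 10 replicate refits (different background/fold seeds; smoke
runs use 3), thresholded at the value maximizing sensitivity +
specificity on pooled held-out-fold scores. Ties go to the *largest*
optimizing observed score by default (`tie="max"`): the smaller predicted
range, erring against commission, which is the conservative choice for
conservation planning; `tie="min"` is available. The binary range is
clipped to the 50-km-buffered MCP of the records.

**Substitution.** Species with < 4 records, or failing the AUC gate, get
the union of sub-basins intersecting their MCP — fine-level basins for
island species (island ranges are bounded), coarse-level otherwise. A
single record's MCP is its point (or vague disc). Every species emerges
with exactly one non-empty range.

## Diversity surfaces

SR is the per-cell species count. WE(cell) = Σ 1/Cᵢ over present species
with Cᵢ counted in analysis-grid cells (not km²), so that Σ_cells WE = S
exactly — an identity the tests enforce to 10⁻⁹·S. CWE = WE/SR is nodata
(not 0) where SR = 0: the ratio is undefined there and coding it 0 would
distort hotspot statistics. Stratified stacks (threatened EN∪VU, NT, LC)
recompute SR/WE on the subset but keep each Cᵢ from the species' full
range, so a species' endemism weight does not change with group membership.

## Hotspot statistics

Spatial weights are binary, default distance-band of 2 cell widths
(centre-to-centre), self included for Gi\*; the band is a configuration
knob recorded in the report, since the appropriate scale depends on the
analysis grid. Moran's I uses the closed-form expectation −1/(n−1) and the
normality-assumption variance; a permutation alternative is provided.
Gi\* follows the standard form

z_j = [Σᵢ w_ij xᵢ − x̄ Σᵢ w_ij] / (S·√[(n Σᵢ w_ij² − (Σᵢ w_ij)²)/(n−1)]),

with S = √(Σx²/n − x̄²). A unit whose neighbourhood spans every cell has a
0/0 statistic and is scored 0 (no local excess is definable). Classes are
right-open: 90% for 1.65 < z ≤ 1.96, 95% for 1.96 < z ≤ 2.58, 99% above —
a z exactly at a boundary falls in the lower class. The bounds are the
two-sided standard-normal quantiles as conventionally printed. Contiguous
(4-connected) significant cells merge into hotspot polygons whose cell
multiset exactly equals the significant set.

## Driver regressions

Fine grids are aggregated to coarse blocks by the mean of finite values;
blocks with land fraction < 0.5 are dropped (exactly 0.5 is retained).
Candidate drivers pass a Pearson |r| < 0.75 and VIF < 5 screen. Stepwise
OLS is bidirectional from the empty model, minimizing
AIC = n·ln(RSS/n) + 2k and stopping at a local minimum; the final model is
refit for t/p-values and R². Note that AIC's fixed +2 penalty admits
spurious predictors with a known nonzero probability even as noise → 0
(the criterion is scale-invariant in the residual), so "selects exactly
the true set" holds only in distributional terms; reported coefficients of
spurious terms vanish.

GWR solves a weighted least squares at every cell centroid with a fixed
Gaussian kernel w(d) = exp(−d²/2b²); b minimizes the hat-matrix AICc

AICc = 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S)

by golden-section search over [min pairwise distance, landscape diameter]
(a bound hit raises a warning). Effective parameters use 2·tr S − tr SᵀS;
adjusted R² uses the effective residual degrees of freedom. The MLR report
carries AICc on the same full-likelihood scale so the two models are
directly comparable; selection inside the stepwise search still uses the
AIC form above. An adaptive kernel is a possible extension; the fixed
kernel is the default because coarse-cell analyses have near-uniform
spatial support.

## Gap overlay and Criterion B

The 10-km overlay flags a coarse cell as hotspot/covered when it
*intersects* any hotspot/reserve polygon (any overlap, not centre-in —
conservative toward protection coverage; switchable); a gap is a hotspot
cell with no reserve overlap, so hotspot = covered + gap by construction.

EOO is the equal-area convex-hull area of a species' sites; collinear or
single sites fall back to the hull buffered by one cell width. AOO counts
distinct occupied 10-km sites × 30 km² per site. Sites may be occupied
analysis cells (SDM mode, the default for modelled ranges) or thinned
localities. Criterion B applies the external IUCN v3.1 thresholds
(B1 EOO < 100/5 000/20 000 km², B2 AOO < 10/500/2 000 km² for CR/EN/VU),
taking the worse of B1/B2, only when the B subconditions (fragmentation /
decline / fluctuation) are asserted; without them the category is marked
"potential". Metrics within 1.5× the VU bound fall to NT, else LC; the
thresholds and margin live in a versioned YAML file, not code. Criterion D
needs population counts and is out of scope; published categories can be
merged as overrides.

## Core-area prioritization

Removal cost of cell j is δ_j = maxᵢ wᵢ·p_ij/rᵢ with rᵢ species i's
remaining presence; the built-environment layer enters additively as
w_built·b_j/Σb (negative, making built-up cells cheaper to remove) — a
deliberate simplification of condition-layer handling, switchable off.
Species weights are 1 below the median range size and 2 at or above it
(the boundary choice is configurable); the built weight is the negative of
the species-weight sum, so all feature weights sum to zero. Reserve cells
form a hierarchical mask: every unmasked cell is removed before any
reserve cell. Ties in δ break to the lowest flat cell index. Removal is
batched (`warp` cells per iteration) with δ recomputed between batches;
the default warp scales as max(1, n_cells/1000) so the batch size keeps
the same proportion of the landscape as a warp of 500 does at ~1-km cells
on a subcontinental grid. A brute-force simulator that recomputes every δ
from scratch each step serves as the oracle: warp-1 ranking matches it
exactly on small grids.

The performance curve evaluates, at each protected fraction f, the
proportion of each species' range inside the top-f cells of the ranking,
and averages over species unweighted. Coverage is reported at 5.7%
(the study region's reserve share), 15% and 30% (policy targets), along
with the reserve-mask-only baseline.

## Problem sizes and determinism

Default test and acceptance runs use a 128 × 128-cell, 20-species
landscape with 3 suitability replicates, a 64 × 64 landscape for model
recovery experiments, and n = 400 for GWR recovery — sizes at which every
statistical claim in the test suite is comfortably resolved while the full
chain runs in seconds. All randomness is driven by numpy Generators seeded
from explicit integers; the acceptance script threads its `--seed` through
every stochastic stage.

## Known limitations

- The suitability model is not MaxEnt: no hinge/threshold features, no
  feature-class tuning. Structure (suitability → threshold → binary) and
  gates are preserved, and externally produced suitability rasters can be
  injected.
- Gi\* is computed on cells (or any raster); the polygon-unit variant of
  hotspot classification operates on classified-richness polygons only via
  rasterization.
- No reprojection/resampling: inputs must arrive on a common grid.
- The Criterion B NT/LC split below the threatened thresholds is a
  documented package convention (1.5× margin), not an IUCN rule.
- Shapefile input is not supported; convert to GeoJSON.
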