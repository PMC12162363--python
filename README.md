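# crabmap

A spatial conservation-biogeography pipeline for data-poor freshwater taxa,
built around the workflow used to map freshwater crab diversity in the south
subtropical-tropical zone of China (STZC): from occurrence records to stacked
binary range maps, diversity and endemism surfaces, statistically classified
hotspots, driver regressions, conservation-gap maps, and core-area
prioritization with performance curves.

## Who it is for

Conservation biogeographers working with taxa where most species have very
few verified localities. The pipeline takes occurrence tables, environmental
covariate rasters, reserve and sub-basin polygons, and a human-footprint
raster, and produces the full chain of products a regional conservation
assessment needs. A synthetic-landscape module generates complete study
systems with known ground truth, so every stage is testable end to end at
desk scale.

## The methods at its core

- **Occurrence cleaning**: vague (coordinate-free) localities become 5-km
  discs; records are deduplicated and thinned to one per 10 × 10 km pixel
  with all retained pairs ≥ 10 km apart (great-circle distance).
- **Range construction**: species with ≥ 4 records get a ridge-penalized
  presence–background logistic model on linear + quadratic covariate
  features, gated at 10-fold cross-validated AUC > 0.75, binarized at the
  threshold maximizing sensitivity + specificity, averaged over replicate
  refits and clipped to the 50-km-buffered minimum convex polygon (MCP).
  Data-poor species (or failed gates) get the *substitution* range: the
  union of hydrological sub-basins intersecting their MCP (fine basins for
  island species, coarse otherwise).
- **Diversity surfaces**: species richness SR; weighted endemism
  WE(cell) = Σᵢ 1/Cᵢ over present species (Cᵢ = species i's occupied cell
  count, so Σ_cells WE = S exactly); corrected weighted endemism
  CWE = WE/SR.
- **Hotspots**: global Moran's I (E[I] = −1/(n−1), normality variance)
  screens for spatial structure; local Getis-Ord Gi\* z-scores are classed
  at 1.65/1.96/2.58 into 90/95/99% confidence hotspots and merged into
  polygons.
- **Drivers**: block aggregation to coarse cells (< 50% land excluded),
  Pearson |r| < 0.75 + VIF < 5 screening, bidirectional stepwise OLS
  minimizing AIC = n·ln(RSS/n) + 2k, and geographically weighted regression
  (GWR) with a fixed Gaussian kernel and AICc-optimal bandwidth.
- **Gaps and Red List**: hotspot × reserve overlay on a 10-km grid flags
  conservation gaps; per species, EOO (convex-hull area) and
  AOO (occupied sites × 30 km²) feed an IUCN Criterion B pre-assessment.
- **Prioritization**: core-area ranking — iteratively remove the cell with
  the smallest max_i wᵢ·qᵢⱼ (qᵢⱼ = share of species i's remaining range in
  cell j), with 1/2 species weights split at the median range size, a
  negative-weight built-environment layer balancing the weight sum to zero,
  reserves as a hierarchical mask removed last, and batched removal (warp
  factor). The ranking induces a performance curve: mean proportion of each
  species' range retained in the top fraction of the landscape.

## Worked example

```python
from crabmap import LandscapeConfig, run_pipeline
from crabmap.prioritization import coverage_at_fraction

res = run_pipeline(LandscapeConfig(seed=1), replicates=3)
print(res.sdm_report.head(6).to_string(index=False))
I, e, var, z, p = res.hotspots.morans
print(f"Moran's I = {I:.3f} (z = {z:.1f}, p = {p:.2g})")
print(f"hotspots: {len(res.hotspots.polygons)} patches, "
      f"{100*res.hotspots.landscape_fraction:.1f}% of the landscape")
print(f"gap overlay: {res.gaps.n_hotspot} hotspot cells, {res.gaps.n_gap} gaps")
print(f"reserve baseline: {100*res.protected_baseline.mean():.1f}% of ranges protected")
print(coverage_at_fraction(res.curve).to_string(index=False))
```

prints (on the default 128 × 128, 20-species synthetic landscape):

```
species  n_records   provenance      auc  threshold  range_cells  range_km2
  sp000          2 substitution      NaN        NaN         1387     1387.0
  sp001          4     modelled 0.975000   0.099374         1999     1999.0
  sp002          2 substitution      NaN        NaN         2510     2510.0
  sp003         15     modelled 0.900000   0.102857         3307     3307.0
  sp004         15     modelled 0.907143   0.079119         2680     2680.0
  sp005          1 substitution      NaN        NaN         2083     2083.0
Moran's I = 0.971 (z = 302.7, p = 0)
hotspots: 8 patches, 26.8% of the landscape
gap overlay: 83 hotspot cells, 62 gaps
reserve baseline: 7.5% of ranges protected
 fraction  mean_retained
    0.057       0.075294
    0.150       0.257869
    0.300       0.502618
```

Reading it: sparse species fall back to sub-basin substitution ranges while
better-sampled ones clear the AUC gate; richness is strongly spatially
clustered (Moran's I ≈ 0.97), a quarter of the landscape classifies as
hotspot at ≥ 90% confidence, three quarters of hotspot cells lack reserve
coverage, and growing protection from the reserve baseline (6% of land,
7.5% of ranges) to the top-ranked 30% of the landscape raises mean range
protection to ~50% — the core-area ranking concentrates protection far
faster than area alone.

A `crabmap` CLI wraps each stage (`synth`, `thin`, `sdm`, `diversity`,
`hotspots`, `drivers`, `prioritize`, `gaps`, `redlist`, `io-info`); run
`crabmap --help`.

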