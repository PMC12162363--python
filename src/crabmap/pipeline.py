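"""End-to-end convenience: synthetic landscape → occurrence cleaning →
ranges → diversity → hotspots → gaps → prioritization → performance curve.

Mainly for smoke tests, the acceptance script, and as a worked example of
how the pieces compose; every stage is also usable on its own with real
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diversity, gaps_redlist, hotspot_stats, occurrence_prep, prioritization, sdm
from .core_io import GridRaster, rasterize
from .synthetic_landscape import LandscapeConfig, SyntheticTruth, generate_landscape, sample_occurrences


@dataclass
class PipelineResult:
    truth: SyntheticTruth
    clean: occurrence_prep.CleanOccurrences
    ranges: dict[str, sdm.BinaryRange]
    sdm_report: pd.DataFrame
    stacks: dict[str, diversity.DiversityStack]
    hotspots: hotspot_stats.HotspotMap
    gaps: gaps_redlist.GapMap
    redlist: pd.DataFrame
    ranking: prioritization.PriorityRanking
    curve: prioritization.PerformanceCurve
    protected_baseline: pd.Series


def run_pipeline(config: LandscapeConfig, thin_km: float = 10.0,
                 replicates: int = 3, gap_grid_km: float = 10.0,
                 band: float = 2.0) -> PipelineResult:
    """Run the whole chain on a synthetic landscape.

    ``replicates`` is the suitability-averaging count (the real-data
    default is 10; smaller values trade precision for speed and are fine
    for smoke runs).
    """
    truth = generate_landscape(config)
    occ = sample_occurrences(truth)
    clean = occurrence_prep.spatial_thin(occ, min_dist_km=thin_km, pixel_km=thin_km)
    covariates = {f"cov{k}": g for k, g in enumerate(truth.covariates)}
    ranges, report = sdm.build_ranges(clean.retained, covariates, truth.subbasins,
                                      island=truth.island, replicates=replicates,
                                      seed=config.seed)
    redlist = gaps_redlist.assess_species(ranges, conditions_met=None)
    categories = {sp: (c if c in diversity.KNOWN_CATEGORIES else "LC")
                  for sp, c in redlist["category"].items()}
    stacks = diversity.stratify(ranges, categories)
    hotspots = hotspot_stats.hotspot_analysis(stacks["ALL"].sr, band=band)
    template = stacks["ALL"].sr
    t = template.transform
    nr, nc = template.shape
    extent = (t.c, t.f + t.e * nr, t.a * nc + t.c, t.f)
    gaps = gaps_redlist.overlay_gaps(hotspots.polygons, truth.reserves,
                                     extent, grid_km=gap_grid_km)
    reserve_mask = rasterize(truth.reserves, template)
    weights = prioritization.assign_weights(ranges)
    ranking = prioritization.caz_rank(ranges, weights, built=truth.footprint,
                                      mask=reserve_mask)
    curve = prioritization.performance_curve(ranking, ranges)
    baseline = gaps_redlist.protected_range_fraction(ranges, truth.reserves)
    return PipelineResult(truth, clean, ranges, report, stacks, hotspots,
                          gaps, redlist, ranking, curve, baseline)


def random_ranking(template: GridRaster, seed: int = 0) -> prioritization.PriorityRanking:
    """Uniform-random removal order; the null baseline for curve comparisons."""
    rng = np.random.default_rng(seed)
    n = template.values.size
    order = rng.permutation(n)
    rank = np.empty(n)
    rank[order] = (np.arange(n) + 1) / n
    return prioritization.PriorityRanking(order, template.like(rank.reshape(template.shape)),
                                          warp=1)
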