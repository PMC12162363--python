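"""Synthetic study systems with known ground truth.

Generates everything the analysis chain consumes — spatially autocorrelated
environmental covariates, species whose true ranges are logistic niche
functions of those covariates with a long-tailed (log-normal) range-size
distribution, spatially biased occurrence sampling with vague records and
duplicates, reserve polygons covering a small landscape fraction, a nested
two-level sub-basin partition, and a built-environment (human footprint)
layer anticorrelated with the first covariate.

The landscape lives in a projected equal-area CRS with metre coordinates so
Euclidean distances and buffer areas are exact; the default cell is 1 km.
All randomness flows from a single seed: a fixed seed reproduces every
artifact exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from shapely.geometry import Point, box

from .core_io import (
    CRS,
    Affine,
    GridRaster,
    VectorLayer,
    validate_occurrences,
    write_occurrences,
    write_raster,
    write_vector,
)

#: Cylindrical equal-area projection code used for all synthetic artifacts.
SYNTH_CRS = CRS("EPSG:6933")


@dataclass
class LandscapeConfig:
    shape: tuple[int, int] = (128, 128)
    cell_km: float = 1.0
    n_species: int = 20
    #: log-normal parameters of true range size in cells; the long tail plus
    #: the sampling rate below makes a sizable fraction of species yield <4
    #: records, as in real record compilations.
    range_log_mean: float = 4.5
    range_log_sd: float = 1.3
    n_covariates: int = 4
    correlation_length: float = 10.0  # cells
    niche_strength: float = 2.0  # scale of per-covariate coefficients
    #: expected occurrence records per occupied cell (Poisson rate).
    sampling_rate: float = 0.08
    sampling_bias: float = 0.5  # 0 = uniform over range, 1 = pure effort field
    fraction_vague: float = 0.10
    vague_radius_km: float = 5.0
    fraction_duplicates: float = 0.05
    n_reserves: int = 10
    reserve_fraction: float = 0.06
    n_basins_coarse: int = 12
    n_basins_fine: int = 60
    island_fraction: float = 0.2
    footprint_correlation: float = -0.6
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 8:
            raise ValueError("grid too small")
        if self.n_species < 1 or self.n_covariates < 1:
            raise ValueError("counts must be positive")
        if self.correlation_length >= min(self.shape) / 2:
            raise ValueError("correlation length must be < min(grid dim)/2")
        if self.reserve_fraction > 0.9:
            raise ValueError("requested reserve fraction > 0.9")

    @property
    def template(self) -> GridRaster:
        cell_m = self.cell_km * 1000.0
        transform = Affine.north_up(0.0, self.shape[0] * cell_m, cell_m, cell_m)
        return GridRaster(np.zeros(self.shape), transform, SYNTH_CRS)


@dataclass
class SyntheticTruth:
    config: LandscapeConfig
    covariates: list[GridRaster]
    suitability: dict[str, GridRaster]
    ranges: dict[str, GridRaster]
    niche_coefficients: dict[str, np.ndarray]
    island: dict[str, bool]
    reserves: VectorLayer | None = None
    subbasins: VectorLayer | None = None
    basin_labels: tuple[np.ndarray, np.ndarray] | None = None  # (level1, level2)
    footprint: GridRaster | None = None
    effort: GridRaster | None = None

    @property
    def species(self) -> list[str]:
        return list(self.ranges)


def _gaussian_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Stationary unit-variance Gaussian random field via FFT synthesis.

    The target correlation is a Gaussian kernel exp(-d²/2L²) built on the
    torus; its spectrum (clamped at 0, renormalized so C(0)=1) filters white
    noise, giving exact stationarity in O(n log n).
    """
    nr, nc = shape
    r = np.minimum(np.arange(nr), nr - np.arange(nr))
    c = np.minimum(np.arange(nc), nc - np.arange(nc))
    d2 = r[:, None] ** 2 + c[None, :] ** 2
    kernel = np.exp(-d2 / (2.0 * length**2))
    spectrum = np.real(np.fft.fft2(kernel))
    spectrum = np.clip(spectrum, 0.0, None)
    spectrum *= kernel.size / spectrum.sum()  # force unit marginal variance
    white = rng.standard_normal(shape)
    fld = np.real(np.fft.ifft2(np.fft.fft2(white) * np.sqrt(spectrum)))
    return fld


def generate_covariates(config: LandscapeConfig) -> list[GridRaster]:
    """Mutually independent unit-variance autocorrelated covariate grids."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    template = config.template
    out = []
    for _ in range(config.n_covariates):
        fld = _gaussian_field(rng, config.shape, config.correlation_length)
        out.append(template.like((fld - fld.mean()) / fld.std()))
    return out


def generate_species_truth(config: LandscapeConfig,
                           covariates: list[GridRaster]) -> SyntheticTruth:
    """Draw per-species niches and carve true ranges from suitability.

    Suitability_i = logistic(α_i + Σ_k β_ik c_k). The true range is the
    top-q_i suitability cells where q_i is a log-normal draw (in cells),
    clipped to [1, 30% of the landscape]; a zero draw is redrawn so every
    species has a non-empty range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    template = config.template
    n_cells = template.values.size
    stack = np.stack([c.values for c in covariates])
    suitability, ranges, coefs, island = {}, {}, {}, {}
    for i in range(config.n_species):
        sp = f"sp{i:03d}"
        beta = rng.normal(0.0, config.niche_strength, size=len(covariates))
        alpha = rng.normal(0.0, 0.5)
        s = expit(alpha + np.tensordot(beta, stack, axes=1))
        size = 0
        while not 1 <= size <= int(0.3 * n_cells):
            size = int(round(rng.lognormal(config.range_log_mean, config.range_log_sd)))
        # top-`size` cells by suitability; ties broken by flat index
        order = np.lexsort((np.arange(n_cells), -s.ravel()))
        rng_grid = np.zeros(n_cells)
        rng_grid[order[:size]] = 1.0
        suitability[sp] = template.like(s)
        ranges[sp] = template.like(rng_grid.reshape(config.shape))
        coefs[sp] = np.concatenate([[alpha], beta])
        island[sp] = bool(rng.random() < config.island_fraction)
    return SyntheticTruth(config, covariates, suitability, ranges, coefs, island)


def generate_effort(config: LandscapeConfig) -> GridRaster:
    """Smooth sampling-effort field rescaled to [0, 1]."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    fld = _gaussian_field(rng, config.shape, 2 * config.correlation_length)
    lo, hi = fld.min(), fld.max()
    return config.template.like((fld - lo) / (hi - lo))


def sample_occurrences(truth: SyntheticTruth,
                       config: LandscapeConfig | None = None) -> pd.DataFrame:
    """Biased occurrence sampling from each species' true range.

    Cell selection probability ∝ (1−bias) + bias·effort(cell). Record count
    per species is 1 + Poisson(range_cells · sampling_rate). A configured
    fraction of rows is duplicated verbatim (to exercise deduplication) and
    a fraction is flagged vague: its coordinates are jittered by at most the
    vagueness radius and the radius is stored alongside.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    if truth.effort is None:
        truth.effort = generate_effort(config)
    effort = truth.effort.values.ravel()
    template = config.template
    cell_m = config.cell_km * 1000.0
    rows = []
    for sp in truth.species:
        presence = truth.ranges[sp].values.ravel() > 0
        cells = np.flatnonzero(presence)
        n = 1 + rng.poisson(len(cells) * config.sampling_rate)
        w = (1.0 - config.sampling_bias) + config.sampling_bias * effort[cells]
        w = w / w.sum()
        picks = rng.choice(cells, size=n, replace=True, p=w)
        r, c = np.unravel_index(picks, config.shape)
        x, y = template.transform.xy(r, c, "center")
        jx = rng.uniform(-0.4, 0.4, size=n) * cell_m
        jy = rng.uniform(-0.4, 0.4, size=n) * cell_m
        for xi, yi in zip(x + jx, y + jy):
            rows.append({"species": sp, "lon": xi, "lat": yi,
                         "vague": False, "source": "synthetic",
                         "vague_radius_km": 0.0})
    table = pd.DataFrame(rows)
    # verbatim duplicates
    n_dup = int(round(config.fraction_duplicates * len(table)))
    if n_dup:
        dup = table.iloc[rng.choice(len(table), size=n_dup, replace=False)]
        table = pd.concat([table, dup], ignore_index=True)
    # vague records: jitter within the vagueness radius, flag, store radius
    n_vague = int(round(config.fraction_vague * len(table)))
    if n_vague:
        idx = rng.choice(len(table), size=n_vague, replace=False)
        radius_m = config.vague_radius_km * 1000.0
        theta = rng.uniform(0, 2 * math.pi, size=n_vague)
        rad = radius_m * np.sqrt(rng.uniform(0, 1, size=n_vague))
        table.loc[idx, "lon"] += rad * np.cos(theta)
        table.loc[idx, "lat"] += rad * np.sin(theta)
        table.loc[idx, "vague"] = True
        table.loc[idx, "vague_radius_km"] = config.vague_radius_km
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return validate_occurrences(table, SYNTH_CRS)


def generate_reserves(config: LandscapeConfig, template: GridRaster | None = None) -> VectorLayer:
    """Random circular reserves whose union covers ≈ the configured fraction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    template = template or config.template
    nr, nc = template.shape
    cell_m = abs(template.transform.a)
    width, height = nc * cell_m, nr * cell_m
    target = config.reserve_fraction * width * height
    mean_r = math.sqrt(target / (math.pi * config.n_reserves))
    landscape = box(0, 0, width, height)
    discs, union, names = [], None, []
    for k in range(20 * config.n_reserves):
        cx, cy = rng.uniform(0, width), rng.uniform(0, height)
        r = mean_r * rng.lognormal(0.0, 0.3)
        disc = Point(cx, cy).buffer(r, quad_segs=32).intersection(landscape)
        if disc.is_empty:
            continue
        new_union = disc if union is None else union.union(disc)
        if union is not None and new_union.area > 1.07 * target:
            continue
        union = new_union
        discs.append(disc)
        names.append(f"NR{len(discs):03d}")
        if union.area >= 0.97 * target:
            break
    attrs = pd.DataFrame({"name": names, "level": 1})
    return VectorLayer(discs, attrs, template.crs)


def generate_subbasins(config: LandscapeConfig,
                       template: GridRaster | None = None):
    """Two-level nested Voronoi partition of the grid.

    Coarse seeds define level-1 basins; fine seeds are each owned by the
    coarse basin containing them, and a cell's level-2 basin is the nearest
    fine seed *within its own level-1 basin*, which guarantees exact nesting.
    Returns (VectorLayer of level-2 basin polygons with level-1 parents,
    level1 label grid, level2 label grid).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    template = template or config.template
    nr, nc = template.shape
    xs, ys = template.cell_centers()
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    cell_m = abs(template.transform.a)
    extent = np.array([nc * cell_m, nr * cell_m])

    coarse = rng.uniform(0, 1, size=(config.n_basins_coarse, 2)) * extent
    fine = rng.uniform(0, 1, size=(config.n_basins_fine, 2)) * extent
    d_coarse = np.linalg.norm(pts[:, None, :] - coarse[None, :, :], axis=2)
    level1 = d_coarse.argmin(axis=1)
    fine_parent = np.linalg.norm(fine[:, None, :] - coarse[None, :, :], axis=2).argmin(axis=1)
    d_fine = np.linalg.norm(pts[:, None, :] - fine[None, :, :], axis=2)
    level2 = np.empty(pts.shape[0], dtype=int)
    for j in range(pts.shape[0]):
        own = np.flatnonzero(fine_parent == level1[j])
        if own.size == 0:  # coarse basin without a fine seed: one basin
            level2[j] = config.n_basins_fine + level1[j]
        else:
            level2[j] = own[d_fine[j, own].argmin()]
    lvl1 = level1.reshape(nr, nc)
    lvl2 = level2.reshape(nr, nc)

    geoms, l1_attr, l2_attr = [], [], []
    t = template.transform
    for lab in np.unique(lvl2):
        rr, cc = np.nonzero(lvl2 == lab)
        boxes = [box(t.a * c + t.c, t.f + t.e * (r + 1),
                     t.a * (c + 1) + t.c, t.f + t.e * r) for r, c in zip(rr, cc)]
        geoms.append(shapely.unary_union(boxes))
        l2_attr.append(int(lab))
        l1_attr.append(int(lvl1[rr[0], cc[0]]))
    attrs = pd.DataFrame({"level2": l2_attr, "level1": l1_attr})
    return VectorLayer(geoms, attrs, template.crs), lvl1, lvl2


def generate_footprint(config: LandscapeConfig,
                       covariates: list[GridRaster]) -> GridRaster:
    """Built-environment intensity in [0,1], anticorrelated with covariate 1."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rho = config.footprint_correlation
    noise = _gaussian_field(rng, config.shape, config.correlation_length)
    base = rho * covariates[0].values + math.sqrt(max(0.0, 1 - rho**2)) * noise
    lo, hi = base.min(), base.max()
    return config.template.like((base - lo) / (hi - lo))


def generate_landscape(config: LandscapeConfig) -> SyntheticTruth:
    """Full synthetic study system: one call, fully seed-determined."""
    covariates = generate_covariates(config)
    truth = generate_species_truth(config, covariates)
    truth.effort = generate_effort(config)
    truth.reserves = generate_reserves(config)
    truth.subbasins, lvl1, lvl2 = generate_subbasins(config)
    truth.basin_labels = (lvl1, lvl2)
    truth.footprint = generate_footprint(config, covariates)
    return truth


def export_landscape(truth: SyntheticTruth, out_dir) -> None:
    """Write all artifacts (GeoTIFF/GeoJSON/CSV + manifest) for the CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, cov in enumerate(truth.covariates):
        write_raster(cov, out / f"covariate_{k}.tif")
    for sp, rng_ in truth.ranges.items():
        write_raster(rng_, out / f"true_range_{sp}.tif")
    if truth.footprint is not None:
        write_raster(truth.footprint, out / "footprint.tif")
    if truth.reserves is not None:
        write_vector(truth.reserves, out / "reserves.geojson")
    if truth.subbasins is not None:
        write_vector(truth.subbasins, out / "subbasins.geojson")
    occ = sample_occurrences(truth)
    write_occurrences(occ, out / "occurrences.csv")
    manifest = pd.DataFrame({
        "species": truth.species,
        "range_cells": [int(truth.ranges[sp].values.sum()) for sp in truth.species],
        "island": [truth.island[sp] for sp in truth.species],
    })
    manifest.to_csv(out / "truth_manifest.csv", index=False)
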