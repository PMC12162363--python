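"""Spatial autocorrelation and hotspot classification.

Global Moran's I (normality-assumption variance, with a permutation option)
tests whether a diversity surface is spatially structured at all; the local
Getis-Ord Gi* statistic then z-scores each unit against the global mean,
and units are classified into 90/95/99% confidence hotspot classes at the
conventional z thresholds 1.65 / 1.96 / 2.58 (right-open: a z exactly at a
boundary falls in the lower class). Contiguous significant cells merge into
hotspot polygons with their total area and landscape fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import sparse
from scipy.ndimage import label as cc_label
from scipy.stats import norm
from shapely.geometry import box

from .core_io import GridRaster, VectorLayer, cell_area_km2

#: (z threshold, class label) — strict lower bounds, right-open intervals.
CLASS_THRESHOLDS = ((2.58, "99%"), (1.96, "95%"), (1.65, "90%"))


@dataclass
class SpatialWeights:
    """Sparse binary weights over the valid cells of a grid."""

    matrix: sparse.csr_matrix  # n_units × n_units
    cells: np.ndarray          # flat indices of valid cells, in matrix order
    scheme: str
    include_self: bool


def grid_weights(raster: GridRaster, scheme: str = "distance-band",
                 band: float = 2.0, include_self: bool = False) -> SpatialWeights:
    """Binary weights among valid cells: queen/rook contiguity or a
    distance band of ``band`` cell widths (centre-to-centre)."""
    nr, nc = raster.shape
    valid = np.flatnonzero(raster.mask.ravel())
    pos = -np.ones(nr * nc, dtype=int)
    pos[valid] = np.arange(len(valid))
    rows, cols = np.unravel_index(valid, raster.shape)
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    elif scheme == "distance-band":
        b = int(np.floor(band))
        offsets = [(dr, dc) for dr in range(-b, b + 1) for dc in range(-b, b + 1)
                   if (dr, dc) != (0, 0) and np.hypot(dr, dc) <= band]
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    ii, jj = [], []
    for dr, dc in offsets:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
        tgt = pos[r2[ok] * nc + c2[ok]]
        src = np.arange(len(valid))[ok]
        keep = tgt >= 0
        ii.append(src[keep])
        jj.append(tgt[keep])
    if include_self:
        ii.append(np.arange(len(valid)))
        jj.append(np.arange(len(valid)))
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    w = sparse.csr_matrix((np.ones(len(ii)), (ii, jj)),
                          shape=(len(valid), len(valid)))
    return SpatialWeights(w, valid, scheme, include_self)


def morans_i(raster: GridRaster, weights: SpatialWeights):
    """Global Moran's I with expectation, normality variance, z and p.

    I = (n/W)·ΣΣ w_ij z_i z_j / Σ z_i², E[I] = −1/(n−1); the variance is the
    closed form under the normality assumption; p is two-sided.
    """
    x = raster.values.ravel()[weights.cells]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 units")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance field")
    W = weights.matrix
    s0 = float(W.sum())
    num = float(z @ (W @ z))
    I = (n / s0) * num / denom
    e_i = -1.0 / (n - 1)
    Wt = W.T.tocsr()
    s1 = 0.5 * float((W + Wt).power(2).sum())
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    zscore = (I - e_i) / np.sqrt(var)
    p = 2 * norm.sf(abs(zscore))
    return I, e_i, var, zscore, p


def morans_i_permutation(raster: GridRaster, weights: SpatialWeights,
                         n_perm: int = 499, seed: int = 0):
    """Randomization inference: permutation distribution of I."""
    rng = np.random.default_rng(seed)
    x = raster.values.ravel()[weights.cells]
    obs = morans_i(raster, weights)[0]
    sims = np.empty(n_perm)
    W = weights.matrix
    n = len(x)
    s0 = float(W.sum())
    for k in range(n_perm):
        z = rng.permutation(x)
        z = z - z.mean()
        sims[k] = (n / s0) * float(z @ (W @ z)) / float(z @ z)
    p = (1 + np.sum(np.abs(sims - sims.mean()) >= abs(obs - sims.mean()))) / (n_perm + 1)
    return obs, sims, p


def gi_star(raster: GridRaster, weights: SpatialWeights) -> GridRaster:
    """Getis-Ord Gi* z-score per cell (weights must include self).

    z_j = [Σ_i w_ji x_i − x̄ Σ_i w_ji] /
          (S · sqrt[(n Σ_i w_ji² − (Σ_i w_ji)²)/(n−1)]),
    S = sqrt(Σ x²/n − x̄²).
    """
    if not weights.include_self:
        raise ValueError("Gi* weights must include self")
    x = raster.values.ravel()[weights.cells]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 units")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise ValueError("zero variance field")
    W = weights.matrix
    wx = W @ x
    wsum = np.asarray(W.sum(axis=1)).ravel()
    wsq = np.asarray(W.power(2).sum(axis=1)).ravel()
    denom = s * np.sqrt(np.maximum(n * wsq - wsum**2, 0.0) / (n - 1))
    num = wx - xbar * wsum
    # a unit whose neighbourhood spans every cell has numerator and
    # denominator both 0: no local excess is definable, score it 0
    with np.errstate(invalid="ignore", divide="ignore"):
        zvals = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.full(raster.values.size, np.nan)
    out[weights.cells] = zvals
    return raster.like(out.reshape(raster.shape))


@dataclass
class HotspotMap:
    z: GridRaster
    classes: GridRaster  # 0 = not significant, 1/2/3 = 90/95/99%
    polygons: VectorLayer
    total_area_km2: float
    landscape_fraction: float
    morans: tuple | None = None


def classify_hotspots(z_grid: GridRaster, morans: tuple | None = None) -> HotspotMap:
    """Assign confidence classes and merge significant cells into polygons."""
    z = z_grid.values
    cls = np.zeros_like(z)
    cls[z > 1.65] = 1
    cls[z > 1.96] = 2
    cls[z > 2.58] = 3
    cls[~np.isfinite(z)] = np.nan
    sig = np.nan_to_num(cls) > 0
    area = cell_area_km2(z_grid).values
    valid = np.isfinite(z)
    total = float(area[sig].sum())
    fraction = float(sig.sum() / valid.sum()) if valid.any() else 0.0
    labels, n_blobs = cc_label(sig)
    t = z_grid.transform
    geoms, attr_rows = [], []
    for lab in range(1, n_blobs + 1):
        rr, cc = np.nonzero(labels == lab)
        boxes = [box(t.a * c + t.c, t.f + t.e * (r + 1),
                     t.a * (c + 1) + t.c, t.f + t.e * r)
                 for r, c in zip(rr, cc)]
        geoms.append(shapely.unary_union(boxes))
        attr_rows.append({"hotspot": lab, "n_cells": len(rr),
                          "area_km2": float(area[rr, cc].sum()),
                          "max_z": float(np.nanmax(z[rr, cc]))})
    import pandas as pd
    polys = VectorLayer(geoms, pd.DataFrame(attr_rows), z_grid.crs) if geoms \
        else VectorLayer([], pd.DataFrame(), z_grid.crs)
    return HotspotMap(z_grid, z_grid.like(cls), polys, total, fraction, morans)


def hotspot_analysis(values: GridRaster, band: float = 2.0) -> HotspotMap:
    """Moran's I screen + Gi* + classification in one call."""
    w_moran = grid_weights(values, "distance-band", band, include_self=False)
    morans = morans_i(values, w_moran)
    w_gi = grid_weights(values, "distance-band", band, include_self=True)
    return classify_hotspots(gi_star(values, w_gi), morans)
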