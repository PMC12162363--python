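"""Species range construction: modelled or substituted.

Each species ends with exactly one non-empty binary range. Species with at
least four records are modelled with a ridge-penalized presence–background
logistic regression on linear+quadratic covariate features (a minimal
stand-in for low-sample maximum-entropy configurations: suitability →
threshold → binary is preserved); the model must clear a cross-validated
AUC > 0.75 gate. The suitability surface, averaged over replicate refits,
is binarized at the threshold maximizing sensitivity + specificity on
held-out folds and clipped to the species' 50-km-buffered minimum convex
polygon. Species with fewer records, or failing the gate, receive the
substitution range: the union of hydrological sub-basins intersecting the
records' MCP (fine basin level for island species, coarse otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from shapely.geometry import MultiPoint

from .core_io import (
    CRS,
    GridRaster,
    VectorLayer,
    assert_aligned,
    cell_area_km2,
    combined_mask,
    rasterize,
)
from .occurrence_prep import _km_to_native, buffer_vague

MIN_RECORDS_FOR_MODEL = 4
AUC_GATE = 0.75
MCP_BUFFER_KM = 50.0


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_rank(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic (ties get half credit)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Variable screening
# ---------------------------------------------------------------------------

@dataclass
class VariableScreenReport:
    correlation: pd.DataFrame
    vif: pd.Series
    retained: list[str]
    contributions: pd.Series


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column regressed on the others."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        y = Xc[:, j]
        others = np.delete(Xc, j, axis=1)
        if others.shape[1] == 0:
            out[j] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(y @ y)
        r2 = 0.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def screen_collinearity(X: np.ndarray, names: list[str], r_max: float,
                        vif_max: float) -> tuple[list[str], pd.DataFrame, pd.Series]:
    """Greedy |r| then VIF elimination; returns survivors + diagnostics.

    While any pair exceeds ``r_max``, the member of the worst pair with the
    higher mean |r| against all other variables is dropped; then the highest-
    VIF variable is dropped until all VIF < ``vif_max``.
    """
    names = list(names)
    corr_full = pd.DataFrame(np.corrcoef(X, rowvar=False), index=names, columns=names)
    keep = list(range(X.shape[1]))
    while len(keep) > 1:
        sub = np.abs(np.corrcoef(X[:, keep], rowvar=False))
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(sub.argmax(), sub.shape)
        if sub[i, j] < r_max:
            break
        drop = i if sub[i].mean() >= sub[j].mean() else j
        keep.pop(drop)
    while len(keep) > 1:
        v = _vif(X[:, keep])
        if v.max() < vif_max:
            break
        keep.pop(int(v.argmax()))
    if not keep:
        raise ValueError("all variables eliminated; increase r_max")
    survivors = [names[k] for k in keep]
    vif = pd.Series(_vif(X[:, keep]) if len(keep) > 1 else [1.0], index=survivors)
    return survivors, corr_full, vif


def screen_variables(covariates: dict[str, GridRaster], records: pd.DataFrame,
                     r_max: float = 0.9, vif_max: float = 5.0,
                     seed: int = 0) -> VariableScreenReport:
    """Collinearity screen over the landscape, then zero-contribution drop.

    Correlations/VIF are computed over all jointly valid cells. Contribution
    is the permutation importance (AUC drop) of each survivor in a quick
    presence–background fit on the supplied records; survivors contributing
    nothing are removed.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two covariates to screen")
    if len(records) < 3:
        raise ValueError("need at least three records to screen")
    names = list(covariates)
    grids = [covariates[n] for n in names]
    mask = combined_mask(*grids)
    X = np.column_stack([g.values[mask] for g in grids])
    survivors, corr, vif = screen_collinearity(X, names, r_max, vif_max)

    model = fit_suitability(records, {n: covariates[n] for n in survivors}, seed=seed)
    rng = np.random.default_rng(seed)
    Xp, y = model.train_X, model.train_y
    base = auc_rank(model.predict_features(Xp)[y == 1], model.predict_features(Xp)[y == 0])
    contrib = {}
    for k, name in enumerate(survivors):
        drops = []
        for _ in range(5):
            Xs = Xp.copy()
            cols = [i for i, f in enumerate(model.feature_of) if f == k]
            perm = rng.permutation(Xs.shape[0])
            Xs[:, cols] = Xs[perm][:, cols]
            s = model.predict_features(Xs)
            drops.append(base - auc_rank(s[y == 1], s[y == 0]))
        contrib[name] = max(0.0, float(np.mean(drops)))
    contributions = pd.Series(contrib)
    final = [n for n in survivors if contributions[n] > 0] or survivors
    return VariableScreenReport(corr, vif, final, contributions)


# ---------------------------------------------------------------------------
# Suitability model
# ---------------------------------------------------------------------------

@dataclass
class SuitabilityModel:
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    regularization_c: float
    fold_aucs: list[float]
    mean_auc: float
    # training state needed for replicate refits and thresholding
    records: pd.DataFrame = field(repr=False, default=None)
    covariate_names: list[str] = field(default_factory=list)
    feature_of: list[int] = field(default_factory=list)  # covariate index per feature
    feat_mean: np.ndarray = field(repr=False, default=None)
    feat_std: np.ndarray = field(repr=False, default=None)
    train_X: np.ndarray = field(repr=False, default=None)  # standardized features
    train_y: np.ndarray = field(repr=False, default=None)
    oof_scores: np.ndarray = field(repr=False, default=None)
    seed: int = 0

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def records_to_cells(records: pd.DataFrame, template: GridRaster) -> np.ndarray:
    """Flat cell index of each record; records off the grid are dropped."""
    t = template.transform
    col = np.floor((records["lon"].to_numpy() - t.c) / t.a).astype(int)
    row = np.floor((records["lat"].to_numpy() - t.f) / t.e).astype(int)
    nr, nc = template.shape
    ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    return np.ravel_multi_index((row[ok], col[ok]), template.shape)


def _features(raw: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Linear + quadratic features; returns design and covariate index map."""
    p = raw.shape[1]
    X = np.column_stack([raw, raw**2])
    feature_of = list(range(p)) + list(range(p))
    return X, feature_of


def fit_suitability(records: pd.DataFrame, covariates: dict[str, GridRaster],
                    background_n: int | None = None, seed: int = 0,
                    k_folds: int = 10) -> SuitabilityModel:
    """Ridge presence–background logistic with cross-validated AUC.

    Background points: min(10 000, 10 × presences) cells drawn uniformly
    from the jointly valid modelling region. The ridge penalty is picked by
    CV AUC over a small grid; per-fold AUCs and pooled out-of-fold scores
    are retained for the downstream threshold rule.
    """
    names = list(covariates)
    grids = [covariates[n] for n in names]
    assert_aligned(*grids)
    template = grids[0]
    cells = records_to_cells(records, template)
    if len(np.unique(cells)) < 2:
        raise ValueError("degenerate training data: all presences in one cell")
    mask_flat = combined_mask(*grids).ravel()
    cells = cells[mask_flat[cells]]
    rng = np.random.default_rng(seed)
    n_bg = background_n or min(10_000, 10 * len(cells))
    bg = rng.choice(np.flatnonzero(mask_flat), size=n_bg, replace=True)
    raw = np.column_stack([g.values.ravel()[np.concatenate([cells, bg])] for g in grids])
    y = np.concatenate([np.ones(len(cells)), np.zeros(len(bg))]).astype(int)
    X, feature_of = _features(raw)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    k = int(min(k_folds, len(cells), n_bg))
    k = max(k, 2)
    best = None
    for C in (0.01, 0.1, 1.0, 10.0):
        fold_aucs, oof = _cv_auc(Xs, y, C, k, seed)
        mean_auc = float(np.mean(fold_aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, C, fold_aucs, oof)
    mean_auc, C, fold_aucs, oof = best
    clf = LogisticRegression(C=C, max_iter=1000)
    clf.fit(Xs, y)
    return SuitabilityModel(
        feature_names=[f"{names[f]}{'_sq' if i >= len(names) else ''}"
                       for i, f in enumerate(feature_of)],
        coefficients=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
        regularization_c=C, fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=mean_auc, records=records, covariate_names=names,
        feature_of=feature_of, feat_mean=mu, feat_std=sd,
        train_X=Xs, train_y=y, oof_scores=oof, seed=seed,
    )


def _cv_auc(Xs, y, C, k, seed):
    """Stratified k-fold CV: per-fold AUC and pooled out-of-fold scores."""
    rng = np.random.default_rng(seed)
    oof = np.full(len(y), np.nan)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        folds[idx] = rng.permutation(len(idx)) % k
    aucs = []
    for f in range(k):
        test = folds == f
        clf = LogisticRegression(C=C, max_iter=1000)
        clf.fit(Xs[~test], y[~test])
        s = clf.predict_proba(Xs[test])[:, 1]
        oof[test] = s
        yt = y[test]
        if yt.min() != yt.max():
            aucs.append(auc_rank(s[yt == 1], s[yt == 0]))
    return aucs, oof


def predict_suitability(model: SuitabilityModel,
                        covariates: dict[str, GridRaster]) -> GridRaster:
    grids = [covariates[n] for n in model.covariate_names]
    assert_aligned(*grids)
    template = grids[0]
    mask = combined_mask(*grids)
    raw = np.column_stack([g.values[mask] for g in grids])
    X, _ = _features(raw)
    Xs = (X - model.feat_mean) / model.feat_std
    out = np.full(template.shape, np.nan)
    out[mask] = model.predict_features(Xs)
    return template.like(out)


# ---------------------------------------------------------------------------
# Thresholding and binary ranges
# ---------------------------------------------------------------------------

def max_sens_spec_threshold(scores: np.ndarray, labels: np.ndarray,
                            tie: str = "max") -> float:
    """Threshold (an observed score) maximizing sensitivity + specificity.

    Presence is predicted where score ≥ threshold. On ties, ``tie='max'``
    picks the largest optimizing score (smaller predicted range; errs
    against commission), ``tie='min'`` the smallest.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cand = np.unique(scores)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    sens = (len(pos) - np.searchsorted(pos, cand, side="left")) / len(pos)
    spec = np.searchsorted(neg, cand, side="left") / len(neg)
    j = sens + spec
    best = np.flatnonzero(j == j.max())
    return float(cand[best.max() if tie == "max" else best.min()])


@dataclass
class BinaryRange:
    species: str
    presence: GridRaster
    provenance: str  # "modelled" | "substitution"
    n_records: int
    threshold: float | None = None
    auc: float | None = None

    def __post_init__(self):
        if self.provenance not in ("modelled", "substitution"):
            raise ValueError("provenance must be modelled or substitution")
        if self.range_cells == 0:
            raise ValueError(f"{self.species}: empty binary range")

    @property
    def range_cells(self) -> int:
        return int(np.nansum(self.presence.values))

    @property
    def range_km2(self) -> float:
        area = cell_area_km2(self.presence).values
        return float(np.nansum(area * (self.presence.values == 1)))


def species_mcp(records: pd.DataFrame, buffer_km: float = 0.0):
    """Minimum convex polygon over record footprints (vague discs included)."""
    buffered = buffer_vague(records)
    crs: CRS = buffered.attrs["crs"]
    hull = shapely.unary_union(list(buffered["footprint"])).convex_hull
    if buffer_km > 0:
        hull = hull.buffer(_km_to_native(buffer_km, crs))
    return hull


def binarize(model: SuitabilityModel, covariates: dict[str, GridRaster],
             replicates: int = 10, tie: str = "max",
             mcp_buffer_km: float = MCP_BUFFER_KM,
             auc_gate: float = AUC_GATE) -> BinaryRange | None:
    """Averaged-replicate binary range, or None to signal substitution.

    Suitability is averaged over ``replicates`` refits with distinct
    background/fold seeds; the threshold maximizes sensitivity+specificity
    on pooled held-out-fold scores; presence is clipped to the 50-km
    buffered MCP of the training records. Returns None when the mean CV AUC
    does not clear the gate.
    """
    if model.mean_auc <= auc_gate:
        return None
    template = covariates[model.covariate_names[0]]
    grids_sum = np.zeros(template.shape)
    scores, labels = [], []
    for rep in range(replicates):
        m = (model if rep == 0 else
             fit_suitability(model.records, covariates, seed=model.seed + 1 + rep))
        grids_sum += np.nan_to_num(predict_suitability(m, covariates).values)
        ok = np.isfinite(m.oof_scores)
        scores.append(m.oof_scores[ok])
        labels.append(m.train_y[ok])
    avg = grids_sum / replicates
    thr = max_sens_spec_threshold(np.concatenate(scores), np.concatenate(labels), tie)
    presence = (avg >= thr).astype(float)
    mask = combined_mask(*[covariates[n] for n in model.covariate_names])
    presence[~mask] = np.nan
    hull = species_mcp(model.records, buffer_km=mcp_buffer_km)
    clip = rasterize(VectorLayer([hull], crs=template.crs), template).values
    presence = np.where(clip == 1, presence, 0.0)
    sp = str(model.records["species"].iloc[0]) if "species" in model.records else "?"
    return BinaryRange(sp, template.like(presence), "modelled",
                       n_records=len(model.records), threshold=thr, auc=model.mean_auc)


def substitution_range(records: pd.DataFrame, subbasins: VectorLayer,
                       template: GridRaster, island: bool = False) -> BinaryRange:
    """Union of sub-basins intersecting the records' MCP.

    Island species use the fine (level-2) basins; mainland species the
    coarse (level-1) groups, formed by dissolving level-2 polygons on their
    parent label.
    """
    if records.empty:
        raise ValueError("substitution_range needs at least one record")
    sp = str(records["species"].iloc[0])
    mcp = species_mcp(records)
    if island or "level1" not in subbasins.attributes.columns:
        units = list(subbasins.geometries)
    else:
        units = [shapely.unary_union([g for g, p in
                                      zip(subbasins.geometries, subbasins.attributes["level1"])
                                      if p == parent])
                 for parent in sorted(subbasins.attributes["level1"].unique())]
    hits = [u for u in units if u.intersects(mcp)]
    if not hits:
        raise ValueError(f"{sp}: no sub-basin intersects the records' MCP")
    layer = VectorLayer(hits, crs=subbasins.crs)
    presence = rasterize(layer, template)
    return BinaryRange(sp, presence, "substitution", n_records=len(records))


def build_ranges(clean_records: pd.DataFrame, covariates: dict[str, GridRaster],
                 subbasins: VectorLayer, island: dict[str, bool] | None = None,
                 replicates: int = 10, seed: int = 0,
                 tie: str = "max") -> tuple[dict[str, BinaryRange], pd.DataFrame]:
    """One BinaryRange per species: modelled if ≥4 records and AUC > 0.75,
    substitution otherwise. Returns (ranges, report table)."""
    island = island or {}
    template = next(iter(covariates.values()))
    ranges: dict[str, BinaryRange] = {}
    rows = []
    for sp, sub in clean_records.groupby("species", sort=True):
        sub = sub.copy()
        sub.attrs["crs"] = clean_records.attrs.get("crs")
        br = None
        auc = np.nan
        if len(sub) >= MIN_RECORDS_FOR_MODEL:
            try:
                model = fit_suitability(sub, covariates, seed=seed)
                auc = model.mean_auc
                br = binarize(model, covariates, replicates=replicates, tie=tie)
            except ValueError as exc:
                warnings.warn(f"{sp}: modelling failed ({exc}); substituting")
        if br is None:
            br = substitution_range(sub, subbasins, template,
                                    island=bool(island.get(sp, False)))
        ranges[sp] = br
        rows.append({"species": sp, "n_records": len(sub), "provenance": br.provenance,
                     "auc": auc, "threshold": br.threshold,
                     "range_cells": br.range_cells, "range_km2": br.range_km2})
    return ranges, pd.DataFrame(rows)
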