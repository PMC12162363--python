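"""Relating diversity surfaces to environmental and human drivers.

The fine grids are first aggregated to coarse analysis cells (0.5° in the
real-data setting; a configurable block size here), dropping cells with
less than half their area on land. Candidate drivers then pass a Pearson
|r| < 0.75 and VIF < 5 collinearity screen, and species richness is
modelled two ways: a bidirectional stepwise ordinary least squares
minimizing AIC = n·ln(RSS/n) + 2k, and a geographically weighted
regression (GWR) — local weighted least squares with a fixed Gaussian
kernel whose bandwidth minimizes the hat-matrix-corrected AICc. The two
reports share a common structure so their AICc/adjusted R² can be compared
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

from .core_io import GridRaster, assert_aligned
from .sdm import screen_collinearity


# ---------------------------------------------------------------------------
# Coarse-cell aggregation
# ---------------------------------------------------------------------------

def aggregate_blocks(grids: dict[str, GridRaster], block: int,
                     land_mask: GridRaster | None = None,
                     min_land_fraction: float = 0.5) -> pd.DataFrame:
    """Block-mean aggregation of aligned fine grids to a coarse cell table.

    Each coarse cell of ``block``×``block`` fine cells gets the mean of its
    finite fine values per grid, a land fraction (share of valid land-mask
    cells), and its centroid coordinates. Cells with land fraction below
    ``min_land_fraction`` are excluded (boundary: exactly 0.5 is retained).
    """
    names = list(grids)
    rasters = [grids[n] for n in names]
    if land_mask is not None:
        rasters = rasters + [land_mask]
    assert_aligned(*rasters)
    template = rasters[0]
    nr, nc = template.shape
    nbr, nbc = nr // block, nc // block
    if nbr == 0 or nbc == 0:
        raise ValueError("block size larger than the grid")
    rows = []
    t = template.transform
    for bi in range(nbr):
        for bj in range(nbc):
            sl = (slice(bi * block, (bi + 1) * block),
                  slice(bj * block, (bj + 1) * block))
            if land_mask is not None:
                land = np.nan_to_num(land_mask.values[sl]) > 0
                frac = float(land.mean())
            else:
                frac = float(np.isfinite(template.values[sl]).mean())
            if frac < min_land_fraction:
                continue
            row = {"row": bi, "col": bj, "land_fraction": frac}
            cx, cy = t.xy(bi * block + block / 2 - 0.5, bj * block + block / 2 - 0.5)
            row["x"], row["y"] = float(cx), float(cy)
            ok = True
            for name in names:
                vals = grids[name].values[sl]
                finite = np.isfinite(vals)
                if not finite.any():
                    ok = False
                    break
                row[name] = float(vals[finite].mean())
            if ok:
                rows.append(row)
    if not rows:
        raise ValueError("no coarse cells survive the land-fraction filter")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pearson screen
# ---------------------------------------------------------------------------

@dataclass
class PearsonScreen:
    correlation: pd.DataFrame
    p_values: pd.DataFrame
    retained: list[str]
    vif: pd.Series


def pearson_matrix(table: pd.DataFrame, variables: list[str],
                   r_max: float = 0.75, vif_max: float = 5.0) -> PearsonScreen:
    """Pairwise Pearson r (with p-values) and the |r|/VIF screened set."""
    X = table[variables].to_numpy(dtype=float)
    p = len(variables)
    corr = np.eye(p)
    pvals = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            r, pv = pearsonr(X[:, i], X[:, j])
            corr[i, j] = corr[j, i] = r
            pvals[i, j] = pvals[j, i] = pv
    retained, _, vif = screen_collinearity(X, variables, r_max, vif_max)
    return PearsonScreen(
        pd.DataFrame(corr, index=variables, columns=variables),
        pd.DataFrame(pvals, index=variables, columns=variables),
        retained, vif,
    )


# ---------------------------------------------------------------------------
# Stepwise multiple linear regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    kind: str  # "MLR" | "GWR"
    selected: list[str]
    coefficients: pd.DataFrame | None
    aic: float
    aicc: float
    r2: float
    adj_r2: float
    rss: float
    bandwidth: float | None = None
    local_coefficients: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def _ols_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(AIC, RSS) of an OLS fit with intercept; AIC = n ln(RSS/n) + 2k."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    k = design.shape[1]
    return n * np.log(rss / n) + 2 * k, rss


def stepwise_mlr(table: pd.DataFrame, response: str,
                 candidates: list[str]) -> RegressionReport:
    """Bidirectional stepwise OLS minimizing AIC = n·ln(RSS/n) + 2k.

    Starting from the empty (intercept-only) model, each round considers
    every single addition and removal and takes the move with the largest
    AIC drop, stopping at a local minimum. The final model is refit with
    statsmodels for t/p-values and R²; AICc is reported alongside.
    """
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    if n < len(candidates) + 10:
        raise ValueError("need ≥ 10 more rows than candidate variables")
    selected: list[str] = []
    current_aic, _ = _ols_aic(y, np.empty((n, 0)))
    while True:
        moves = []
        for var in candidates:
            if var in selected:
                trial = [v for v in selected if v != var]
            else:
                trial = selected + [var]
            aic, _ = _ols_aic(y, table[trial].to_numpy(dtype=float))
            moves.append((aic, trial))
        best_aic, best_set = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current_aic, selected = best_aic, best_set
        else:
            break
    design = sm.add_constant(table[selected].to_numpy(dtype=float)) \
        if selected else np.ones((n, 1))
    fit = sm.OLS(y, design).fit()
    if selected and np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design after selection")
    k = design.shape[1]
    rss = float(fit.ssr)
    aic = n * np.log(rss / n) + 2 * k
    # AICc on the full Gaussian-likelihood scale (hat-matrix trace = k for
    # OLS), so it is directly comparable with the GWR report
    aicc = (2 * n * np.log(np.sqrt(rss / n)) + n * np.log(2 * np.pi)
            + n * (n + k) / max(n - 2 - k, 1))
    names = ["intercept"] + selected
    coef = pd.DataFrame({"coefficient": fit.params, "t": fit.tvalues,
                         "p": fit.pvalues}, index=names)
    return RegressionReport("MLR", selected, coef, aic, aicc,
                            float(fit.rsquared), float(fit.rsquared_adj), rss)


# ---------------------------------------------------------------------------
# Geographically weighted regression
# ---------------------------------------------------------------------------

def _gwr_fit(y: np.ndarray, X: np.ndarray, coords: np.ndarray, bandwidth: float):
    """Local Gaussian-kernel WLS at every point; returns (beta, hat, yhat)."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    betas = np.empty((n, p + 1))
    hat = np.empty((n, n))
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    wts = np.exp(-d2 / (2.0 * bandwidth**2))
    for i in range(n):
        w = wts[i]
        Xw = design * w[:, None]
        A = design.T @ Xw
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        proj = Ainv @ Xw.T            # (p+1) × n
        betas[i] = proj @ y
        hat[i] = design[i] @ proj
    yhat = (design * betas).sum(axis=1)
    return betas, hat, yhat


def _gwr_aicc(y: np.ndarray, yhat: np.ndarray, hat: np.ndarray) -> float:
    """Hat-matrix AICc: 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S)."""
    n = len(y)
    rss = float(((y - yhat) ** 2).sum())
    tr_s = float(np.trace(hat))
    sigma = np.sqrt(rss / n)
    denom = n - 2.0 - tr_s
    if denom <= 0:
        return np.inf
    return 2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + tr_s) / denom


def gwr(table: pd.DataFrame, response: str, variables: list[str],
        bandwidth: float | None = None) -> RegressionReport:
    """GWR with fixed Gaussian kernel and AICc-optimal bandwidth.

    Bandwidth is selected by golden-section search on the hat-matrix AICc
    over [min positive pairwise distance, landscape diameter]; a warning is
    issued if the optimum sits at a search bound. Effective parameters use
    2·tr(S) − tr(SᵀS); adjusted R² uses the effective residual dof.
    """
    y = table[response].to_numpy(dtype=float)
    X = table[variables].to_numpy(dtype=float)
    coords = table[["x", "y"]].to_numpy(dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("GWR needs at least 30 rows")
    notes = []
    if bandwidth is None:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        pos = d[d > 0]
        lo, hi = float(pos.min()), float(d.max())
        phi = (np.sqrt(5) - 1) / 2
        a, b = lo, hi
        c1, c2 = b - phi * (b - a), a + phi * (b - a)
        f = {}

        def crit(bw):
            if bw not in f:
                _, hat, yhat = _gwr_fit(y, X, coords, bw)
                f[bw] = _gwr_aicc(y, yhat, hat)
            return f[bw]

        for _ in range(40):
            if crit(c1) < crit(c2):
                b, c2 = c2, c1
                c1 = b - phi * (b - a)
            else:
                a, c1 = c1, c2
                c2 = a + phi * (b - a)
            if b - a < 1e-6 * (hi - lo):
                break
        bandwidth = (a + b) / 2
        if bandwidth < lo * 1.01 or bandwidth > hi * 0.99:
            notes.append(f"bandwidth search hit bound: {bandwidth:.6g}")
            warnings.warn(notes[-1])
    betas, hat, yhat = _gwr_fit(y, X, coords, bandwidth)
    rss = float(((y - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    tr_s = float(np.trace(hat))
    tr_sts = float((hat * hat).sum())
    enp = 2 * tr_s - tr_sts
    r2 = 1 - rss / tss
    adj_r2 = 1 - (rss / max(n - enp, 1e-9)) / (tss / (n - 1))
    aicc = _gwr_aicc(y, yhat, hat)
    aic = 2 * n * np.log(np.sqrt(rss / n)) + n * np.log(2 * np.pi) + 2 * (enp + 1)
    local = pd.DataFrame(betas, columns=["intercept"] + list(variables))
    local[["x", "y"]] = coords
    return RegressionReport("GWR", list(variables), None, aic, aicc, r2,
                            float(adj_r2), rss, bandwidth=float(bandwidth),
                            local_coefficients=local, notes=notes)
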