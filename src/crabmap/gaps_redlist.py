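"""Conservation-gap overlay and geographic-range Red List metrics.

Gaps: hotspot polygons and reserve polygons are overlaid on a coarse
(10-km) square grid; a grid cell is a hotspot cell if it intersects any
hotspot polygon, covered if it intersects any reserve, and a conservation
gap if it is a hotspot cell with no reserve overlap.

Red List: per species, EOO is the equal-area convex-hull area of its sites
(degenerate hulls fall back to a one-cell-width buffer of the line/point),
AOO is the count of distinct occupied 10-km sites × 30 km², and a
Criterion B category is derived from the external IUCN threshold table
(B1 on EOO, B2 on AOO, worse of the two) when the B subconditions hold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import MultiPoint, box
from shapely.strtree import STRtree

from .core_io import CRS, GridRaster, VectorLayer, rasterize
from .occurrence_prep import _km_to_native
from .sdm import BinaryRange

CATEGORY_ORDER = ["LC", "NT", "VU", "EN", "CR"]
SITE_AREA_KM2 = 30.0


def _load_thresholds() -> dict:
    with resources.files("crabmap.data").joinpath("iucn_criterion_b.yaml").open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Gap overlay
# ---------------------------------------------------------------------------

@dataclass
class GapMap:
    cells: pd.DataFrame  # row, col, geometry index flags: hotspot, covered, gap
    grid_km: float
    n_hotspot: int
    n_covered: int
    n_gap: int

    @property
    def covered_fraction(self) -> float:
        return self.n_covered / self.n_hotspot if self.n_hotspot else float("nan")


def overlay_gaps(hotspots: VectorLayer, reserves: VectorLayer,
                 extent: tuple[float, float, float, float],
                 grid_km: float = 10.0) -> GapMap:
    """Overlay hotspot and reserve polygons on a coarse square grid.

    ``extent`` is (xmin, ymin, xmax, ymax) in the layers' CRS. A cell
    counts as hotspot/covered when it intersects any polygon of the
    respective layer (any overlap, not centre-in); gap = hotspot & not
    covered.
    """
    if len(hotspots) and len(reserves) and hotspots.crs != reserves.crs:
        raise ValueError("hotspot and reserve layers must share a CRS")
    crs = hotspots.crs if len(hotspots) else reserves.crs
    step = _km_to_native(grid_km, crs)
    xmin, ymin, xmax, ymax = extent
    nx = max(1, int(np.ceil((xmax - xmin) / step)))
    ny = max(1, int(np.ceil((ymax - ymin) / step)))
    if len(hotspots) == 0:
        warnings.warn("overlay_gaps: empty hotspot layer")
        empty = pd.DataFrame(columns=["row", "col", "hotspot", "covered", "gap"])
        return GapMap(empty, grid_km, 0, 0, 0)
    hs_tree = STRtree(hotspots.geometries)
    rs_tree = STRtree(reserves.geometries) if len(reserves) else None
    rows = []
    for i in range(ny):
        for j in range(nx):
            cell = box(xmin + j * step, ymin + i * step,
                       xmin + (j + 1) * step, ymin + (i + 1) * step)
            hs = any(hotspots.geometries[k].intersects(cell)
                     for k in hs_tree.query(cell))
            if not hs:
                continue
            cov = bool(rs_tree is not None and any(
                reserves.geometries[k].intersects(cell)
                for k in rs_tree.query(cell)))
            rows.append({"row": i, "col": j, "hotspot": True,
                         "covered": cov, "gap": not cov})
    cells = pd.DataFrame(rows)
    n_hot = len(cells)
    n_cov = int(cells["covered"].sum()) if n_hot else 0
    return GapMap(cells, grid_km, n_hot, n_cov, n_hot - n_cov)


def protected_range_fraction(ranges: dict[str, BinaryRange],
                             reserves: VectorLayer) -> pd.Series:
    """Per-species share of presence cells whose centre lies in a reserve."""
    template = next(iter(ranges.values())).presence
    if len(reserves) == 0:
        return pd.Series({sp: 0.0 for sp in sorted(ranges)})
    reserve_grid = rasterize(reserves, template).values
    out = {}
    for sp in sorted(ranges):
        pres = np.nan_to_num(ranges[sp].presence.values) > 0
        out[sp] = float((reserve_grid[pres] > 0).mean()) if pres.any() else 0.0
    return pd.Series(out)


# ---------------------------------------------------------------------------
# EOO / AOO and Criterion B
# ---------------------------------------------------------------------------

@dataclass
class RedListRecord:
    species: str
    eoo_km2: float
    aoo_km2: float
    n_sites: int
    category: str
    criterion: str
    potential: bool = False  # True when subcondition flags were not supplied


def eoo_aoo(points_xy: np.ndarray, crs: CRS, site_area_km2: float = SITE_AREA_KM2,
            site_grid_km: float = 10.0, cell_width_km: float = 1.0):
    """(EOO km², AOO km², n_sites) from site coordinates.

    EOO is the convex-hull area (equal-area CRS assumed for projected
    input); collinear or single sites fall back to the hull buffered by one
    cell width. AOO counts distinct occupied ``site_grid_km`` pixels, each
    worth ``site_area_km2``.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise ValueError("need at least one site")
    to_km = 1.0 / _km_to_native(1.0, crs)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    area_native = hull.area
    if area_native == 0.0:  # point or line: buffer by one cell width
        hull = hull.buffer(_km_to_native(cell_width_km, crs))
        area_native = hull.area
    eoo = area_native * to_km**2
    step = _km_to_native(site_grid_km, crs)
    sites = {(int(np.floor(x / step)), int(np.floor(y / step))) for x, y in pts}
    aoo = len(sites) * site_area_km2
    return float(eoo), float(aoo), len(sites)


def criterion_b_category(eoo_km2: float, aoo_km2: float,
                         conditions_met: bool | None = None,
                         thresholds: dict | None = None) -> tuple[str, str, bool]:
    """(category, criterion string, potential flag) under Criterion B.

    B1 classifies on EOO, B2 on AOO; the worse (more threatened) of the two
    wins and the criterion string records which applied. Threatened
    categories require the B subconditions; with ``conditions_met=None``
    the category is computed as a 'potential' assessment. Below-NT-margin
    metrics fall to NT, everything else to LC.
    """
    th = thresholds or _load_thresholds()
    if eoo_km2 < 0 or aoo_km2 < 0:
        raise ValueError("EOO/AOO must be ≥ 0")
    potential = conditions_met is None
    if conditions_met is False:
        nt = (eoo_km2 < th["b1_eoo_km2"]["VU"] * th["nt_margin"]
              or aoo_km2 < th["b2_aoo_km2"]["VU"] * th["nt_margin"])
        return ("NT" if nt else "LC"), "", False

    def level(value, table):
        for cat in ("CR", "EN", "VU"):
            if value < table[cat]:
                return cat
        return None

    b1 = level(eoo_km2, th["b1_eoo_km2"])
    b2 = level(aoo_km2, th["b2_aoo_km2"])
    cats = [c for c in (b1, b2) if c]
    if cats:
        cat = max(cats, key=CATEGORY_ORDER.index)
        parts = []
        if b1 == cat:
            parts.append("B1ab(iii)")
        if b2 == cat:
            parts.append("B2ab(iii)")
        return cat, "+".join(parts), potential
    nt = (eoo_km2 < th["b1_eoo_km2"]["VU"] * th["nt_margin"]
          or aoo_km2 < th["b2_aoo_km2"]["VU"] * th["nt_margin"])
    return ("NT" if nt else "LC"), "", potential


def assess_species(ranges: dict[str, BinaryRange],
                   conditions_met: bool | None = None,
                   site_area_km2: float = SITE_AREA_KM2,
                   overrides: pd.Series | dict | None = None) -> pd.DataFrame:
    """Criterion B pre-assessment for every species from its binary range.

    Sites are the occupied analysis cells (SDM mode). ``overrides`` merges
    externally supplied categories (e.g., published assessments) on top.
    """
    overrides = dict(overrides or {})
    rows = []
    for sp in sorted(ranges):
        br = ranges[sp]
        pres = np.nan_to_num(br.presence.values) > 0
        rr, cc = np.nonzero(pres)
        t = br.presence.transform
        xs = t.a * (cc + 0.5) + t.c
        ys = t.f + t.e * (rr + 0.5)
        cell_km = abs(t.a) / _km_to_native(1.0, br.presence.crs)
        eoo, aoo, n_sites = eoo_aoo(np.column_stack([xs, ys]), br.presence.crs,
                                    site_area_km2, cell_width_km=cell_km)
        eoo = max(eoo, cell_km**2)
        cat, crit, potential = criterion_b_category(eoo, aoo, conditions_met)
        if sp in overrides:
            cat, crit, potential = str(overrides[sp]), "override", False
        rows.append(RedListRecord(sp, eoo, aoo, n_sites, cat, crit, potential))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("species")
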