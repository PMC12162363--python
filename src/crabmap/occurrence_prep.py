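"""Occurrence record cleaning: vague-locality buffering, deduplication,
and spatial thinning.

Records lacking precise coordinates ("vague") carry a locality point and a
vagueness radius; :func:`buffer_vague` turns them into discs usable for
sub-basin intersection. :func:`spatial_thin` enforces, per species, at most
one record per coarse pixel and a minimum pairwise great-circle distance,
with a deterministic retention rule. Every removal is logged with exactly
one reason so that |input| = |retained| + |removed| always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .core_io import CRS, haversine_km, pairwise_distance_km, validate_occurrences

REMOVAL_REASONS = ("duplicate", "within-thinning-radius", "outlier")


@dataclass
class CleanOccurrences:
    retained: pd.DataFrame
    removals: pd.DataFrame  # columns: original index, species, reason

    def __post_init__(self):
        if len(self.removals) and not set(self.removals["reason"]) <= set(REMOVAL_REASONS):
            raise ValueError("unknown removal reason")


def _km_to_native(km: float, crs: CRS, lat: float = 0.0) -> float:
    """Convert a km length to the CRS's native unit (degrees or metres)."""
    if crs.is_geographic:
        # one degree of longitude at `lat` on the authalic sphere
        from .core_io import EARTH_RADIUS_KM
        return km / (np.pi / 180.0 * EARTH_RADIUS_KM * max(np.cos(np.radians(lat)), 1e-6))
    return km * 1000.0


def buffer_vague(records: pd.DataFrame, radius_km: float = 5.0) -> pd.DataFrame:
    """Attach a shapely footprint to every record.

    Precise records footprint as their point; vague records as a disc of
    their stored vagueness radius (falling back to ``radius_km``). Vague
    records without a locality are dropped with a logged reason column.
    """
    records = validate_occurrences(records, records.attrs.get("crs"))
    crs: CRS = records.attrs["crs"]
    footprints = []
    keep = []
    for _, row in records.iterrows():
        if not np.isfinite(row["lon"]) or not np.isfinite(row["lat"]):
            keep.append(False)
            footprints.append(None)
            continue
        keep.append(True)
        pt = Point(row["lon"], row["lat"])
        if row["vague"]:
            r = float(row.get("vague_radius_km", 0.0) or radius_km)
            if r <= 0:
                footprints.append(pt)
            else:
                footprints.append(pt.buffer(_km_to_native(r, crs, row["lat"]), quad_segs=64))
        else:
            footprints.append(pt)
    out = records.loc[keep].copy()
    out["footprint"] = [f for f, k in zip(footprints, keep) if k]
    out.attrs["crs"] = crs
    return out


def _thin_one_species(sub: pd.DataFrame, crs: CRS, min_dist_km: float,
                      pixel_km: float) -> tuple[list, list[tuple[int, str]]]:
    """Returns (retained original indices, [(removed index, reason), ...])."""
    removed: list[tuple[int, str]] = []
    # 1. exact-coordinate duplicates: keep the first occurrence (by index)
    sub = sub.sort_index()
    dup = sub.duplicated(subset=["lon", "lat"], keep="first")
    removed += [(i, "duplicate") for i in sub.index[dup]]
    sub = sub.loc[~dup]
    # 2. one record per coarse pixel
    if pixel_km and pixel_km > 0 and len(sub) > 1:
        px = _km_to_native(pixel_km, crs)
        pixel = (np.floor(sub["lon"].to_numpy() / px).astype(int),
                 np.floor(sub["lat"].to_numpy() / px).astype(int))
        key = pd.Series(list(zip(*pixel)), index=sub.index)
        dup = key.duplicated(keep="first")
        removed += [(i, "within-thinning-radius") for i in sub.index[dup]]
        sub = sub.loc[~dup]
    # 3. greedy radius thinning: visit records by descending local density
    #    (neighbour count within min_dist), then by index; keep-first
    if min_dist_km and min_dist_km > 0 and len(sub) > 1:
        d = pairwise_distance_km(sub["lon"].to_numpy(), sub["lat"].to_numpy(), crs)
        density = (d < min_dist_km).sum(axis=1) - 1
        order = np.lexsort((np.arange(len(sub)), -density))
        kept_pos: list[int] = []
        for pos in order:
            if all(d[pos, q] >= min_dist_km for q in kept_pos):
                kept_pos.append(pos)
            else:
                removed.append((sub.index[pos], "within-thinning-radius"))
        retained_idx = sorted(sub.index[kept_pos])
    else:
        retained_idx = list(sub.index)
    return retained_idx, removed


def spatial_thin(records: pd.DataFrame, min_dist_km: float = 10.0,
                 pixel_km: float = 10.0, outlier_km: float | None = None) -> CleanOccurrences:
    """Deduplicate and spatially thin records per species.

    Applies, in order: exact-duplicate removal, one-record-per-pixel
    (``pixel_km`` grid), then greedy minimum-distance thinning so all
    retained pairs are ≥ ``min_dist_km`` apart (great-circle for geographic
    CRS). ``outlier_km``, if given, first drops records farther than that
    from the species' coordinate centroid.
    """
    records = validate_occurrences(records, records.attrs.get("crs"))
    crs: CRS = records.attrs["crs"]
    if records.empty:
        return CleanOccurrences(records, pd.DataFrame(columns=["index", "species", "reason"]))
    retained_parts, removal_rows = [], []
    for sp, sub in records.groupby("species", sort=True):
        if outlier_km is not None and len(sub) > 2:
            cx, cy = sub["lon"].mean(), sub["lat"].mean()
            if crs.is_geographic:
                d0 = haversine_km(sub["lon"], sub["lat"], cx, cy)
            else:
                d0 = np.hypot(sub["lon"] - cx, sub["lat"] - cy) / 1000.0
            far = d0 > outlier_km
            removal_rows += [(i, sp, "outlier") for i in sub.index[far]]
            sub = sub.loc[~far]
        idx, removed = _thin_one_species(sub, crs, min_dist_km, pixel_km)
        retained_parts.append(records.loc[idx])
        removal_rows += [(i, sp, reason) for i, reason in removed]
    retained = pd.concat(retained_parts).sort_index() if retained_parts else records.iloc[:0]
    retained.attrs["crs"] = crs
    removals = pd.DataFrame(removal_rows, columns=["index", "species", "reason"])
    assert len(retained) + len(removals) == len(records)
    return CleanOccurrences(retained, removals)
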