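"""Raster/vector I/O and the shared grid geometry model.

Every gridded quantity in the pipeline lives in a :class:`GridRaster`: a
single-band, north-up, row-major grid with an affine placement and a CRS.
Rasters entering a joint computation must share shape, transform and CRS
exactly — alignment is checked and never silently repaired by resampling.
Nodata is represented internally as NaN and propagates through every stage.

GeoTIFF support is implemented directly on top of tifffile using the
standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA). Vector layers are shapely geometries
serialized as GeoJSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

#: Authalic sphere radius in km (sphere with the same surface area as the
#: WGS84 ellipsoid); used for all great-circle distances and geographic areas.
EARTH_RADIUS_KM = 6371.0072

# EPSG codes treated as geographic (degree) systems; everything else is
# assumed projected with metre units.
_GEOGRAPHIC_EPSG = {4326, 4269, 4490, 4019, 4258}

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_KEY_GT_MODEL_TYPE = 1024
_KEY_GT_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


class CRSError(ValueError):
    pass


class AlignmentError(ValueError):
    """Two rasters with different shape/transform/CRS met in one stage."""


@dataclass(frozen=True)
class CRS:
    """Minimal coordinate reference model: an EPSG code string.

    Geographic systems are recognized by code; all other codes are assumed
    to be projected with metre units (the pipeline's equal-area workhorse).
    """

    code: str

    def __post_init__(self):
        if not self.code or ":" not in self.code:
            raise CRSError(f"CRS code must look like 'EPSG:4326', got {self.code!r}")

    @property
    def epsg(self) -> int:
        return int(self.code.split(":")[1])

    @property
    def is_geographic(self) -> bool:
        return self.epsg in _GEOGRAPHIC_EPSG

    def __eq__(self, other):
        return isinstance(other, CRS) and self.epsg == other.epsg

    def __hash__(self):
        return hash(self.epsg)


class Affine(NamedTuple):
    """North-up affine: x = a*col + c, y = e*row + f at pixel corners.

    ``(c, f)`` is the outer corner of pixel (0, 0) — the northwest corner of
    the grid; ``a > 0`` and ``e < 0`` (row index grows southward).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, west: float, north: float, xres: float, yres: float) -> "Affine":
        return cls(xres, 0.0, west, 0.0, -abs(yres), north)

    def xy(self, row, col, offset: str = "center"):
        """Map coordinates of a pixel; offset='center' or 'corner'."""
        dr = dc = 0.5 if offset == "center" else 0.0
        col = np.asarray(col, dtype=float) + dc
        row = np.asarray(row, dtype=float) + dr
        return self.a * col + self.c, self.e * row + self.f

    def approx_equal(self, other: "Affine", tol: float = 1e-9) -> bool:
        return all(abs(s - o) <= tol * max(1.0, abs(s)) for s, o in zip(self, other))


@dataclass
class GridRaster:
    """Single-band georeferenced grid. Nodata cells are NaN in ``values``."""

    values: np.ndarray
    transform: Affine
    crs: CRS
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("GridRaster values must be 2-D")
        if self.transform.b != 0 or self.transform.d != 0 or self.transform.e >= 0:
            raise ValueError("only north-up, non-rotated grids are supported")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid: True where data is valid (finite)."""
        return np.isfinite(self.values)

    def cell_centers(self):
        """(x, y) coordinate grids of all cell centers."""
        rows, cols = np.indices(self.shape)
        return self.transform.xy(rows, cols, "center")

    def like(self, values: np.ndarray) -> "GridRaster":
        """New raster with the same geometry and different values."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.shape:
            raise AlignmentError(
                f"replacement values shape {values.shape} != raster shape {self.shape}"
            )
        return replace(self, values=values)

    def aligned_with(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and self.transform.approx_equal(other.transform)
            and self.crs == other.crs
        )


def assert_aligned(*rasters: GridRaster) -> None:
    """Raise AlignmentError unless all rasters share geometry exactly."""
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.aligned_with(r):
            raise AlignmentError(
                "rasters are not aligned: "
                f"{ref.shape}/{ref.transform}/{ref.crs.code} vs "
                f"{r.shape}/{r.transform}/{r.crs.code}; resample inputs explicitly"
            )


def combined_mask(*rasters: GridRaster) -> np.ndarray:
    """Joint validity mask: a cell is valid only if valid in every input."""
    assert_aligned(*rasters)
    m = rasters[0].mask.copy()
    for r in rasters[1:]:
        m &= r.mask
    return m


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(raster: GridRaster, path) -> None:
    """Write a single-band GeoTIFF; NaN cells are stored as the nodata value."""
    values = raster.values.copy()
    values[~np.isfinite(values)] = raster.nodata
    t = raster.transform
    if raster.crs.is_geographic:
        geokeys = [(_KEY_GT_MODEL_TYPE, 0, 1, 2), (_KEY_GT_RASTER_TYPE, 0, 1, 1),
                   (_KEY_GEOGRAPHIC_TYPE, 0, 1, raster.crs.epsg)]
    else:
        geokeys = [(_KEY_GT_MODEL_TYPE, 0, 1, 1), (_KEY_GT_RASTER_TYPE, 0, 1, 1),
                   (_KEY_PROJECTED_CS_TYPE, 0, 1, raster.crs.epsg)]
    directory = [1, 1, 0, len(geokeys)]
    for key in geokeys:
        directory.extend(key)
    nodata_ascii = (repr(float(raster.nodata)) + "\x00").encode()
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.a, -t.e, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0), True),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory), True),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii, True),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def read_raster(path) -> GridRaster:
    """Read a single-band GeoTIFF written with standard geo tags."""
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-page TIFF; expected a single band")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-band raster; expected a single band")
        values = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise CRSError(f"{path}: missing georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        if _TAG_GEO_KEY_DIRECTORY not in tags:
            raise CRSError(f"{path}: missing CRS (no GeoKeyDirectory tag)")
        directory = list(tags[_TAG_GEO_KEY_DIRECTORY].value)
        epsg = None
        geographic = None
        for i in range(4, len(directory), 4):
            key, _, _, value = directory[i : i + 4]
            if key == _KEY_GT_MODEL_TYPE:
                geographic = value == 2
            elif key in (_KEY_GEOGRAPHIC_TYPE, _KEY_PROJECTED_CS_TYPE):
                epsg = value
        if epsg is None:
            raise CRSError(f"{path}: CRS code not found in GeoKeyDirectory")
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).split("\x00")[0])
        values[values == nodata] = np.nan
        transform = Affine.north_up(tie[3] - tie[0] * scale[0],
                                    tie[4] + tie[1] * scale[1],
                                    scale[0], scale[1])
        crs = CRS(f"EPSG:{epsg}")
        if geographic is not None and geographic != crs.is_geographic:
            warnings.warn(f"{path}: GeoKey model type disagrees with EPSG code class")
        return GridRaster(values, transform, crs, nodata=nodata)


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------

@dataclass
class VectorLayer:
    """Polygons/points with attributes; invalid geometries repaired on load."""

    geometries: list
    attributes: pd.DataFrame = field(default_factory=pd.DataFrame)
    crs: CRS = CRS("EPSG:4326")

    def __post_init__(self):
        if len(self.attributes) == 0 and len(self.geometries) > 0:
            self.attributes = pd.DataFrame(index=range(len(self.geometries)))
        if len(self.attributes) != len(self.geometries):
            raise ValueError("attributes and geometries length mismatch")
        repaired = []
        for geom in self.geometries:
            if geom is None or geom.is_empty:
                raise ValueError("empty geometry in VectorLayer")
            repaired.append(geom if geom.is_valid else make_valid(geom))
        self.geometries = repaired

    def __len__(self):
        return len(self.geometries)

    def union(self):
        return shapely.unary_union(self.geometries) if self.geometries else None


def write_vector(layer: VectorLayer, path) -> None:
    features = []
    records = layer.attributes.to_dict("records") if len(layer) else []
    for geom, props in zip(layer.geometries, records or [{}] * len(layer)):
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(geom)})
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": f"urn:ogc:def:crs:EPSG::{layer.crs.epsg}"}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_vector(path) -> VectorLayer:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    crs = CRS("EPSG:4326")
    if "crs" in doc:
        name = doc["crs"]["properties"]["name"]
        crs = CRS("EPSG:" + name.rsplit(":", 1)[-1])
    geometries = [shape(f["geometry"]) for f in doc["features"]]
    attributes = pd.DataFrame([f.get("properties") or {} for f in doc["features"]])
    return VectorLayer(geometries, attributes, crs)


# ---------------------------------------------------------------------------
# Rasterization and areas
# ---------------------------------------------------------------------------

def rasterize(layer: VectorLayer, template: GridRaster, touch_rule: str = "center") -> GridRaster:
    """Burn polygons onto the template grid: 1 where a cell center is inside."""
    if touch_rule != "center":
        raise NotImplementedError("only touch_rule='center' is supported")
    if layer.crs != template.crs:
        raise CRSError(f"layer CRS {layer.crs.code} != template CRS {template.crs.code}")
    out = np.zeros(template.shape, dtype=np.float64)
    if len(layer) == 0:
        warnings.warn("rasterize: empty layer, returning all zeros")
        return template.like(out)
    union = layer.union()
    xs, ys = template.cell_centers()
    inside = shapely.contains_xy(union, xs.ravel(), ys.ravel())
    out.ravel()[inside] = 1.0
    return template.like(out)


def cell_area_km2(raster: GridRaster) -> GridRaster:
    """Per-cell area in km².

    Projected CRS (metre units): constant |xres*yres|/1e6. Geographic CRS:
    per-row spherical quadrangle area R²·Δλ·(sin φ_n − sin φ_s) on the
    authalic sphere.
    """
    t = raster.transform
    nrows, ncols = raster.shape
    if not raster.crs.is_geographic:
        area = abs(t.a * t.e) / 1e6
        return raster.like(np.full(raster.shape, area))
    lat_edges = t.f + t.e * np.arange(nrows + 1)
    phi = np.radians(lat_edges)
    dlam = math.radians(abs(t.a))
    row_area = EARTH_RADIUS_KM**2 * dlam * np.abs(np.sin(phi[:-1]) - np.sin(phi[1:]))
    return raster.like(np.repeat(row_area[:, None], ncols, axis=1))


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "vague", "source"]


def validate_occurrences(table: pd.DataFrame, crs: CRS | None = None) -> pd.DataFrame:
    """Check schema and coordinate ranges; returns the table with clean dtypes."""
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    table = table.copy()
    table["species"] = table["species"].astype(str)
    if (table["species"].str.len() == 0).any():
        raise ValueError("empty species_id in occurrence table")
    table["vague"] = table["vague"].astype(bool)
    for c in ("lon", "lat"):
        table[c] = table[c].astype(float)
    crs = crs or table.attrs.get("crs") or CRS("EPSG:4326")
    if crs.is_geographic:
        if not ((table["lon"].between(-180, 180)) & (table["lat"].between(-90, 90))).all():
            raise ValueError("coordinates out of range for a geographic CRS")
    table.attrs["crs"] = crs
    return table


def read_occurrences(path, crs: CRS | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_occurrences(table, crs)


def write_occurrences(table: pd.DataFrame, path) -> None:
    cols = [c for c in table.columns if c in OCCURRENCE_COLUMNS or c == "vague_radius_km"]
    table.to_csv(path, index=False, columns=cols)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance on the authalic sphere, in km. Vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def pairwise_distance_km(lon, lat, crs: CRS) -> np.ndarray:
    """All-pairs distance matrix honouring the CRS (km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if crs.is_geographic:
        return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    dx = (lon[:, None] - lon[None, :]) / 1000.0
    dy = (lat[:, None] - lat[None, :]) / 1000.0
    return np.hypot(dx, dy)
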