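"""Woodland geometry as discrete source units.

Woodland polygons (planar, metric coordinates) are discretized on a square
grid (default 100 m) and each pixel carries the wooded area it covers,
split into a peripheral *edge* band (default the first 100 m inside the
woodland boundary) and the deeper *core*.  Sampling points then interact
with the landscape only through point-to-pixel-center distances and the
per-pixel source areas, which is what the dispersal model consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as _geom_mapping
from shapely.geometry import shape as _geom_shape
from shapely.ops import unary_union

RESOLUTION_DEFAULT = 100.0  # m
EDGE_BAND_DEFAULT = 100.0  # m
CUTOFF_DEFAULT = 5000.0  # m

RASTER_COLUMNS = ["x_center", "y_center", "area_edge", "area_core"]


class GeometryError(ValueError):
    """Raised for woodland input that violates the planar-metric contract."""


@dataclass(frozen=True)
class SamplingPoint:
    """One crop sampling location (planar metric coordinates, m)."""

    point_id: str
    field_id: str
    site_id: str
    x: float
    y: float


class SourceDistances(NamedTuple):
    """Distances (m) and selected source areas (m2) from a point to pixels."""

    distance: np.ndarray
    area: np.ndarray
    index: np.ndarray


@dataclass
class WoodRaster:
    """Rasterized woodlands: pixel centers with edge/core wooded areas.

    ``x``/``y`` are pixel centers (m), ``area_edge``/``area_core`` wooded
    areas (m2) within the pixel.  Rows are kept in canonical order
    (y then x ascending).
    """

    resolution: float
    x: np.ndarray
    y: np.ndarray
    area_edge: np.ndarray
    area_core: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.area_edge = np.asarray(self.area_edge, dtype=float)
        self.area_core = np.asarray(self.area_core, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.area_edge) == len(self.area_core)):
            raise ValueError("raster arrays must have equal length")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.x):
            if (self.area_edge < 0).any() or (self.area_core < 0).any():
                raise ValueError("pixel areas must be non-negative")
            cap = self.resolution**2 * (1 + 1e-9)
            if (self.area_edge + self.area_core > cap).any():
                raise ValueError("pixel wooded area exceeds the pixel size")
            for arr in (self.x, self.y):
                frac = (arr - arr.min()) / self.resolution
                if not np.allclose(frac, np.round(frac), atol=1e-6):
                    raise ValueError("pixel centers must lie on a regular lattice")
            order = np.lexsort((self.x, self.y))
            self.x = self.x[order]
            self.y = self.y[order]
            self.area_edge = self.area_edge[order]
            self.area_core = self.area_core[order]
            centers = set(zip(self.x.tolist(), self.y.tolist()))
            if len(centers) != len(self.x):
                raise ValueError("duplicate pixel centers")

    @property
    def n_pixels(self) -> int:
        return len(self.x)

    @property
    def area_total(self) -> np.ndarray:
        return self.area_edge + self.area_core

    def select_area(self, origin: str) -> np.ndarray:
        """Source area per pixel for an origin hypothesis: whole wooded
        ``area`` or only the peripheral ``edge`` band."""
        if origin == "area":
            return self.area_total
        if origin == "edge":
            return self.area_edge
        raise ValueError(f"unknown origin {origin!r} (expected 'area' or 'edge')")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_center": self.x,
                "y_center": self.y,
                "area_edge": self.area_edge,
                "area_core": self.area_core,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, resolution: float | None = None) -> "WoodRaster":
        df = pd.read_csv(path)
        missing = [c for c in RASTER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pixel table missing columns: {missing}")
        if resolution is None:
            resolution = _infer_resolution(df["x_center"].to_numpy(), df["y_center"].to_numpy())
        return cls(
            resolution=resolution,
            x=df["x_center"].to_numpy(),
            y=df["y_center"].to_numpy(),
            area_edge=df["area_edge"].to_numpy(),
            area_core=df["area_core"].to_numpy(),
        )


def _infer_resolution(x: np.ndarray, y: np.ndarray) -> float:
    deltas = []
    for arr in (x, y):
        u = np.unique(arr)
        if len(u) > 1:
            deltas.append(np.diff(u).min())
    if not deltas:
        return RESOLUTION_DEFAULT
    return float(min(deltas))


def _as_geometry(polygons):
    if polygons is None:
        geoms = []
    elif isinstance(polygons, shapely.Geometry):
        geoms = [polygons]
    else:
        geoms = list(polygons)
    if not geoms:
        return shapely.Polygon()
    geom = unary_union(geoms)
    if geom.is_empty:
        return geom
    minx, miny, maxx, maxy = geom.bounds
    looks_geographic = (
        -180.0 <= minx <= maxx <= 180.0
        and -90.0 <= miny <= maxy <= 90.0
        and max(maxx - minx, maxy - miny) < 10.0
    )
    if looks_geographic:
        raise GeometryError(
            "woodland coordinates look geographic (lat/lon); supply projected "
            "planar coordinates in meters (e.g. UTM)"
        )
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


def classify_edge_core(
    polygons,
    band: float = EDGE_BAND_DEFAULT,
    resolution: float = RESOLUTION_DEFAULT,
) -> WoodRaster:
    """Rasterize woodlands, splitting each pixel's wooded area into the
    peripheral ``band``-wide edge and the remaining core.

    The edge/core split is done on the vector side (negative buffering of
    the polygon union) before clipping to pixel squares, so the areas are
    exact up to the polygon representation and independent of resolution.
    The grid is anchored at the coordinate origin: pixel (i, j) covers
    [i*res, (i+1)*res) x [j*res, (j+1)*res).
    """
    if band < 0:
        raise ValueError("edge band width must be non-negative")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    geom = _as_geometry(polygons)
    empty = WoodRaster(resolution, np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    if geom.is_empty:
        return empty
    core_geom = geom.buffer(-band) if band > 0 else geom
    edge_geom = geom.difference(core_geom) if band > 0 else shapely.Polygon()

    minx, miny, maxx, maxy = geom.bounds
    i0 = math.floor(minx / resolution)
    i1 = math.ceil(maxx / resolution)
    j0 = math.floor(miny / resolution)
    j1 = math.ceil(maxy / resolution)
    xs = np.arange(i0, i1) * resolution
    ys = np.arange(j0, j1) * resolution
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    cells = shapely.box(gx, gy, gx + resolution, gy + resolution)
    if band > 0:
        a_edge = shapely.area(shapely.intersection(cells, edge_geom))
        a_core = shapely.area(shapely.intersection(cells, core_geom))
    else:
        a_edge = np.zeros(len(cells))
        a_core = shapely.area(shapely.intersection(cells, geom))
    total = a_edge + a_core
    keep = total > resolution**2 * 1e-12
    if not keep.any():
        return empty
    return WoodRaster(
        resolution=resolution,
        x=gx[keep] + resolution / 2,
        y=gy[keep] + resolution / 2,
        area_edge=a_edge[keep],
        area_core=a_core[keep],
    )


def rasterize_woodlands(polygons, resolution: float = RESOLUTION_DEFAULT) -> WoodRaster:
    """Rasterize woodlands without an edge/core split (all area in core)."""
    return classify_edge_core(polygons, band=0.0, resolution=resolution)


def source_distances(
    point: SamplingPoint,
    raster: WoodRaster,
    cutoff: float = CUTOFF_DEFAULT,
    origin: str = "area",
) -> SourceDistances:
    """Euclidean distances (m) from a sampling point to every pixel center
    with positive selected source area within ``cutoff`` (inclusive)."""
    area = raster.select_area(origin)
    d = np.hypot(raster.x - point.x, raster.y - point.y)
    mask = (area > 0) & (d <= cutoff)
    idx = np.nonzero(mask)[0]
    return SourceDistances(distance=d[idx], area=area[idx], index=idx)


def buffer_wood_area(
    point: SamplingPoint,
    raster: WoodRaster,
    radius: float,
    origin: str = "area",
) -> float:
    """Total selected wooded area (m2) of pixels whose centers fall within
    ``radius`` (m) of the point."""
    if radius <= 0:
        raise ValueError("buffer radius must be positive")
    src = source_distances(point, raster, cutoff=radius, origin=origin)
    return float(src.area.sum())


def merge_field_points(points: Sequence[SamplingPoint]) -> SamplingPoint:
    """Collapse one field's sampling points to their unweighted barycenter."""
    if not points:
        raise ValueError("need at least one point to merge")
    fields = {p.field_id for p in points}
    if len(fields) != 1:
        raise ValueError(f"points belong to multiple fields: {sorted(fields)}")
    sites = {p.site_id for p in points}
    if len(sites) != 1:
        raise ValueError(f"points belong to multiple sites: {sorted(sites)}")
    if len(points) == 1:
        return points[0]
    return SamplingPoint(
        point_id=f"{points[0].field_id}:barycenter",
        field_id=points[0].field_id,
        site_id=points[0].site_id,
        x=float(np.mean([p.x for p in points])),
        y=float(np.mean([p.y for p in points])),
    )


def read_woodland_geojson(path) -> list:
    """Read woodland polygons from a GeoJSON FeatureCollection (planar
    metric coordinates required)."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") == "FeatureCollection":
        geoms = [_geom_shape(f["geometry"]) for f in payload.get("features", [])]
    elif payload.get("type") == "GeometryCollection":
        geoms = [_geom_shape(g) for g in payload.get("geometries", [])]
    else:
        geoms = [_geom_shape(payload)]
    for g in geoms:
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"unsupported geometry type {g.geom_type}")
    return geoms


def write_woodland_geojson(polygons: Iterable, path) -> None:
    features = [
        {"type": "Feature", "properties": {}, "geometry": _geom_mapping(g)}
        for g in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def load_woodlands(path, resolution: float = RESOLUTION_DEFAULT,
                   band: float = EDGE_BAND_DEFAULT) -> WoodRaster:
    """Load woodlands from GeoJSON (rasterized here) or a pixel-table CSV."""
    p = str(path)
    if p.endswith((".geojson", ".json")):
        return classify_edge_core(read_woodland_geojson(path), band=band, resolution=resolution)
    return WoodRaster.read_csv(path)
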