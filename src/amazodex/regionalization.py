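"""Analysis units: sub-basin selection, biome clipping, and the equal-area grid.

Drainage basins come as a nested hierarchy (coarse levels subdivide into
finer ones).  Analysis basins are chosen either by descending each branch
to the deepest level whose basins all clear an area threshold (default
30,000 km2, avoiding very small units in the finely subdivided west), or
by taking an explicit level per longitudinal zone.  Selected basins are
clipped to the biome boundary and their areas recomputed on the sphere.
Richness maps use a 50 x 50 km grid built in a cylindrical equal-area
projection centred on the biome.

Areas are spherical (authalic radius R = 6371 km) rather than
ellipsoidal; the difference is far below the granularity of the area
threshold.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import transform
from shapely.strtree import STRtree

from .core import OccurrenceRecord, RegionPolygon, RegionSet

__all__ = [
    "EARTH_RADIUS_KM",
    "polygon_area_km2",
    "select_subbasins",
    "clip_and_area",
    "EqualAreaProjection",
    "build_grid",
    "assign_records",
]

EARTH_RADIUS_KM = 6371.0

#: Edge densification step (degrees) before projecting; keeps the planar
#: shoelace area of long lon/lat edges close to the true spherical value.
_DENSIFY_DEG = 0.05


def _cea_forward(lon, lat):
    """Lambert cylindrical equal-area (standard parallel 0), km units."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.radians(lon)
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat))
    return x, y


def polygon_area_km2(geometry) -> float:
    """Surface area of a lon/lat polygon on the sphere, in km2.

    Edges are densified in lon/lat space, projected with a cylindrical
    equal-area map, and measured with the planar shoelace formula; holes
    are respected.  Invariant to ring orientation and vertex rotation.
    """
    if geometry.is_empty:
        return 0.0
    dense = geometry.segmentize(_DENSIFY_DEG)
    return float(transform(_cea_forward, dense).area)


def clip_and_area(region: RegionPolygon, biome: RegionPolygon) -> Optional[RegionPolygon]:
    """Intersect a region with the biome and recompute its spherical area.

    Returns None when the intersection is empty (region entirely outside).
    """
    inter = region.geometry.intersection(biome.geometry)
    if inter.is_empty:
        return None
    return RegionPolygon(
        region_id=region.region_id,
        name=region.name,
        level=region.level,
        parent_id=region.parent_id,
        geometry=inter,
        area_km2=polygon_area_km2(inter),
    )


def select_subbasins(
    hierarchy: RegionSet,
    mode: str = "auto",
    min_area_km2: float = 30000.0,
    zone_levels: Optional[list[tuple[Polygon, int]]] = None,
    biome: Optional[RegionPolygon] = None,
) -> RegionSet:
    """Choose analysis basins from a nested hierarchy.

    mode="auto": per branch, descend while every child basin's (clipped)
    area exceeds ``min_area_km2``; otherwise stop at the current node, so
    the selection partitions the hierarchy with no overlaps.
    mode="zonal": ``zone_levels`` is a list of (zone polygon, level);
    basins of that level whose centroid falls in the zone are selected.
    """
    roots = [r for r in hierarchy if r.parent_id is None or r.parent_id not in hierarchy]
    if not roots:
        raise ValueError("hierarchy has no root regions")

    def area_of(region: RegionPolygon) -> float:
        if biome is not None:
            clipped = clip_and_area(region, biome)
            return 0.0 if clipped is None else clipped.area_km2
        if not region.area_km2:
            region.area_km2 = polygon_area_km2(region.geometry)
        return region.area_km2

    selected: list[RegionPolygon] = []
    if mode == "auto":
        def descend(node: RegionPolygon) -> None:
            children = hierarchy.children_of(node.region_id)
            if children and all(area_of(c) > min_area_km2 for c in children):
                for c in children:
                    descend(c)
            else:
                selected.append(node)

        for root in roots:
            descend(root)
    elif mode == "zonal":
        if not zone_levels:
            raise ValueError("zonal mode requires zone_levels")
        for zone_geom, level in zone_levels:
            candidates = [
                r for r in hierarchy.at_level(level)
                if zone_geom.covers(r.geometry.representative_point())
            ]
            if not candidates:
                raise ValueError(f"no level-{level} basin found in zone {zone_geom.bounds}")
            selected.extend(candidates)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = RegionSet()
    for region in sorted(selected, key=lambda r: r.region_id):
        if biome is not None:
            clipped = clip_and_area(region, biome)
            if clipped is None:
                continue
            out.add(clipped)
        else:
            if not region.area_km2:
                region.area_km2 = polygon_area_km2(region.geometry)
            out.add(region)
    return out


class EqualAreaProjection:
    """Lambert cylindrical equal-area projection with a chosen centre.

    Standard parallel at the centre latitude, so distances near the biome
    centre are close to true; areas are exact everywhere.  Units: km.
    """

    def __init__(self, center_lon: float, center_lat: float):
        self.center_lon = float(center_lon)
        self.cos_phi_s = math.cos(math.radians(center_lat))

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = EARTH_RADIUS_KM * np.radians(lon - self.center_lon) * self.cos_phi_s
        y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / self.cos_phi_s
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.center_lon + np.degrees(x / (EARTH_RADIUS_KM * self.cos_phi_s))
        lat = np.degrees(np.arcsin(np.clip(y * self.cos_phi_s / EARTH_RADIUS_KM, -1.0, 1.0)))
        return lon, lat


def build_grid(biome: RegionPolygon, cell_size_km: float = 50.0) -> RegionSet:
    """Tile the biome with equal-area square cells (default 50 x 50 km).

    Cells tile the projected bounding box from its minimum corner; cells
    not intersecting the biome are discarded.  Cell ids are ``g<row>_<col>``.
    """
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")
    centroid = biome.geometry.centroid
    proj = EqualAreaProjection(centroid.x, centroid.y)
    projected = transform(proj.forward, biome.geometry.segmentize(_DENSIFY_DEG))
    minx, miny, maxx, maxy = projected.bounds
    n_cols = max(1, math.ceil((maxx - minx) / cell_size_km))
    n_rows = max(1, math.ceil((maxy - miny) / cell_size_km))
    cells = RegionSet()
    for row in range(n_rows):
        for col in range(n_cols):
            cell = box(
                minx + col * cell_size_km,
                miny + row * cell_size_km,
                minx + (col + 1) * cell_size_km,
                miny + (row + 1) * cell_size_km,
            )
            if not cell.intersects(projected):
                continue
            lonlat = transform(proj.inverse, cell.segmentize(cell_size_km / 10.0))
            cells.add(
                RegionPolygon(
                    region_id=f"g{row:03d}_{col:03d}",
                    name=f"cell ({row}, {col})",
                    level=0,
                    geometry=lonlat,
                    area_km2=cell_size_km**2,
                )
            )
    return cells


def assign_records(
    records: Iterable[OccurrenceRecord], regions: RegionSet
) -> tuple[dict[str, str], list[str]]:
    """Assign each record's point to a region by containment (closed boundary).

    Points on a shared border go to the lowest region_id for determinism.
    Returns (record_id -> region_id, list of unassigned record_ids).
    """
    region_list = list(regions)
    tree = STRtree([r.geometry for r in region_list])
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for rec in records:
        if not rec.has_coordinates:
            unassigned.append(rec.record_id)
            continue
        pt = Point(rec.longitude, rec.latitude)
        idx = tree.query(pt, predicate="intersects")
        candidates = sorted(region_list[i].region_id for i in idx)
        if candidates:
            assignment[rec.record_id] = candidates[0]
        else:
            unassigned.append(rec.record_id)
    return assignment, unassigned
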