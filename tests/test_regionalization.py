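"""Basin selection, clipping, the equal-area grid, and record assignment."""

import math

import pytest
from shapely.geometry import Polygon, box

from amazodex.core import RegionPolygon, RegionSet
from amazodex.regionalization import (
    EARTH_RADIUS_KM,
    build_grid,
    clip_and_area,
    polygon_area_km2,
    select_subbasins,
    assign_records,
)
from amazodex.synth import GeneratorConfig, generate_landscape
from conftest import make_record


def zone_area_km2(lon_w, lat_s, lon_e, lat_n):
    """Spherical zone closed form: R^2 * dlambda * (sin phi2 - sin phi1)."""
    return (
        EARTH_RADIUS_KM**2
        * math.radians(lon_e - lon_w)
        * (math.sin(math.radians(lat_n)) - math.sin(math.radians(lat_s)))
    )


@pytest.mark.parametrize(
    "bounds",
    [(0, 0, 1, 1), (-70, -10, -60, 5), (10, 40, 30, 60), (0, -80, 10, -70)],
)
def test_polygon_area_matches_zone_formula(bounds):
    w, s, e, n = bounds
    assert polygon_area_km2(box(w, s, e, n)) == pytest.approx(
        zone_area_km2(w, s, e, n), rel=0.005
    )


def test_polygon_area_invariant_to_ring_order():
    ring = [(0, 0), (2, 0), (2, 1), (0, 1)]
    a = polygon_area_km2(Polygon(ring))
    assert polygon_area_km2(Polygon(ring[::-1])) == pytest.approx(a, rel=1e-9)
    rotated = ring[2:] + ring[:2]
    assert polygon_area_km2(Polygon(rotated)) == pytest.approx(a, rel=1e-9)


def test_polygon_area_respects_holes():
    outer = box(0, 0, 2, 2)
    holed = Polygon(outer.exterior.coords, holes=[box(0.5, 0.5, 1.5, 1.5).exterior.coords])
    assert polygon_area_km2(holed) == pytest.approx(
        polygon_area_km2(outer) - polygon_area_km2(box(0.5, 0.5, 1.5, 1.5)), rel=1e-6
    )


def _two_level_hierarchy(parent_bounds, n_children):
    """Parent at level 1 split into vertical strips at level 2."""
    w, s, e, n = parent_bounds
    regions = RegionSet()
    parent = box(w, s, e, n)
    regions.add(RegionPolygon("p", "parent", level=1, geometry=parent,
                              area_km2=polygon_area_km2(parent)))
    dx = (e - w) / n_children
    for i in range(n_children):
        child = box(w + i * dx, s, w + (i + 1) * dx, n)
        regions.add(RegionPolygon(f"c{i}", f"child {i}", level=2, parent_id="p",
                                  geometry=child, area_km2=polygon_area_km2(child)))
    return regions


def test_select_auto_descends_when_children_qualify():
    # 10x10 degrees near the equator: each of 2 children ~ 600k km2 > threshold
    hierarchy = _two_level_hierarchy((-70, -5, -60, 5), 2)
    selected = select_subbasins(hierarchy, mode="auto", min_area_km2=30000)
    assert sorted(r.region_id for r in selected) == ["c0", "c1"]


def test_select_auto_stops_at_parent_when_leaves_too_small():
    # parent ~ 45,000 km2; each of 2 leaves ~ 22,500 km2 < 30,000 -> parent wins
    side = math.sqrt(45000.0) / 111.0  # rough degrees near the equator
    hierarchy = _two_level_hierarchy((0, 0, side, side), 2)
    parent_area = hierarchy["p"].area_km2
    leaf_area = hierarchy["c0"].area_km2
    assert leaf_area < 30000 < parent_area
    selected = select_subbasins(hierarchy, mode="auto", min_area_km2=30000)
    assert [r.region_id for r in selected] == ["p"]


def test_select_single_qualifying_basin():
    hierarchy = RegionSet()
    geom = box(0, 0, 3, 3)
    hierarchy.add(RegionPolygon("only", level=1, geometry=geom,
                                area_km2=polygon_area_km2(geom)))
    selected = select_subbasins(hierarchy, mode="auto")
    assert [r.region_id for r in selected] == ["only"]


def test_select_zonal_levels():
    hierarchy = _two_level_hierarchy((-70, -5, -60, 5), 2)
    west = box(-70, -5, -65, 5)
    east = box(-65, -5, -60, 5)
    selected = select_subbasins(
        hierarchy, mode="zonal", zone_levels=[(west, 2), (east, 1)]
    )
    assert sorted(r.region_id for r in selected) == ["c0", "p"]
    with pytest.raises(ValueError, match="no level-3 basin"):
        select_subbasins(hierarchy, mode="zonal", zone_levels=[(west, 3)])


def test_selected_basins_partition_biome():
    config = GeneratorConfig(seed=5)
    landscape = generate_landscape(config)
    biome = landscape["biome"]
    hierarchy = RegionSet([r for r in landscape if r.level >= 1])
    selected = select_subbasins(hierarchy, mode="auto", biome=biome)
    total = sum(r.area_km2 for r in selected)
    assert total == pytest.approx(biome.area_km2, rel=0.01)


def test_clip_and_area():
    biome = RegionPolygon("biome", geometry=box(0, 0, 10, 10))
    inside = RegionPolygon("in", geometry=box(1, 1, 3, 3),
                           area_km2=polygon_area_km2(box(1, 1, 3, 3)))
    clipped = clip_and_area(inside, biome)
    assert clipped.area_km2 == pytest.approx(inside.area_km2, rel=1e-4)
    # half in, half out: area halves
    half = RegionPolygon("half", geometry=box(-2, 0, 2, 2))
    clipped = clip_and_area(half, biome)
    assert clipped.area_km2 == pytest.approx(
        polygon_area_km2(box(-2, 0, 2, 2)) / 2.0, rel=0.005
    )
    assert clip_and_area(RegionPolygon("out", geometry=box(20, 20, 21, 21)), biome) is None


def test_grid_cell_counts():
    # a biome projecting to ~100 x 100 km at the equator -> 2x2 = 4 cells
    side_deg = 100.0 / (EARTH_RADIUS_KM * math.pi / 180.0)
    biome = RegionPolygon("biome", geometry=box(0, 0, side_deg, side_deg))
    assert len(build_grid(biome, cell_size_km=50.0)) == 4
    tiny = RegionPolygon("biome", geometry=box(0, 0, 0.01, 0.01))
    assert len(build_grid(tiny, cell_size_km=50.0)) == 1
    with pytest.raises(ValueError):
        build_grid(biome, cell_size_km=0.0)


def test_grid_assignment_is_a_partition():
    biome = RegionPolygon("biome", geometry=box(-61, -3, -59, -1))
    grid = build_grid(biome, cell_size_km=50.0)
    records = [
        make_record(f"r{i}", lat=-3 + 2 * (i % 10) / 10 + 0.05, lon=-61 + 2 * (i // 10) / 10 + 0.05)
        for i in range(100)
    ]
    assignment, unassigned = assign_records(records, grid)
    assert not unassigned
    assert len(assignment) == 100  # every record in exactly one cell


def test_assignment_tie_break_lowest_region_id():
    left = RegionPolygon("a_left", geometry=box(0, 0, 1, 1))
    right = RegionPolygon("b_right", geometry=box(1, 0, 2, 1))
    rec = make_record("edge", lat=0.5, lon=1.0)  # on the shared border
    for order in ([left, right], [right, left]):
        assignment, _ = assign_records([rec], RegionSet(order))
        assert assignment["edge"] == "a_left"


def test_point_at_cell_center(unit_square):
    grid = build_grid(unit_square, cell_size_km=200.0)  # single cell
    (cell,) = list(grid)
    center = cell.geometry.centroid
    assignment, _ = assign_records(
        [make_record("c", lat=center.y, lon=center.x)], grid
    )
    assert assignment["c"] == cell.region_id
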