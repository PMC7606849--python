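"""Boundary extraction chain: rank filter, binarization, Moore tracing,
radial scanning-line simplification and polygon metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uavcanopy.canopy import (
    CanopyMask,
    CanopyPolygon,
    binarize,
    extract_phenotypes,
    extract_plant,
    polygon_metrics,
    radial_scan,
    smooth_chm,
    trace_boundary,
)
from uavcanopy.errors import (
    DegenerateCanopyError,
    EmptyCanopyError,
    InvalidParameterError,
    InvalidPolygonError,
)
from uavcanopy.geometry import GridGeometry

from conftest import disk_mask, make_grid


def shoelace(pts):
    """Independent perimeter/area oracle for a closed polygon."""
    pts = np.asarray(pts, float)
    nxt = np.roll(pts, -1, axis=0)
    per = np.sum(np.hypot(*(nxt - pts).T))
    area = 0.5 * abs(np.sum(pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]))
    return per, area


def rank_oracle(values, window, q):
    """Naive sliding-window sort with reflect padding."""
    k = math.ceil(q * window * window)
    pad = window // 2
    padded = np.pad(values, pad, mode="symmetric")  # scipy "reflect" duplicates the edge
    out = np.empty_like(values, dtype=float)
    for r in range(values.shape[0]):
        for c in range(values.shape[1]):
            block = padded[r : r + window, c : c + window]
            out[r, c] = np.sort(block.ravel())[k - 1]
    return out


# ---------------------------------------------------------------- smoothing

def test_smooth_constant_grid_is_unchanged():
    grid = make_grid(np.full((9, 9), 1.37))
    np.testing.assert_allclose(smooth_chm(grid).values, 1.37)


def test_smooth_center_of_1_to_25_is_seventh_order_statistic():
    grid = make_grid(np.arange(1, 26, dtype=float).reshape(5, 5))
    assert smooth_chm(grid).values[2, 2] == 7.0  # k = ceil(0.25 * 25)


def test_smooth_matches_naive_sliding_window_sort(rng):
    values = rng.uniform(0, 2, size=(20, 20))
    grid = make_grid(values)
    np.testing.assert_allclose(smooth_chm(grid).values, rank_oracle(values, 5, 0.25))


def test_smooth_rejects_even_window():
    with pytest.raises(InvalidParameterError):
        smooth_chm(make_grid(np.zeros((6, 6))), window=4)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_smoothing_never_increases_global_max(seed):
    values = np.random.default_rng(seed).uniform(0, 3, size=(12, 12))
    grid = make_grid(values)
    assert smooth_chm(grid).values.max() <= values.max()


# --------------------------------------------------------------- binarizing

def test_binarize_below_threshold_is_background():
    mask = binarize(make_grid(np.full((4, 4), 0.05)))
    assert not mask.values.any()


def test_binarize_threshold_value_itself_is_canopy():
    mask = binarize(make_grid(np.array([[0.10]])))
    assert mask.values[0, 0]


def test_binarize_foreground_count_matches_brute_force(rng):
    values = rng.uniform(0, 0.3, size=(15, 15))
    mask = binarize(make_grid(values), threshold=0.10)
    assert mask.values.sum() == int(np.sum(values >= 0.10))


# ----------------------------------------------------------------- tracing

def test_trace_3x3_block_gives_ordered_8_cell_ring():
    values = np.zeros((5, 5))
    values[1:4, 1:4] = 1.0
    mask = binarize(make_grid(values, cell_size=1.0), threshold=0.5)
    boundary = trace_boundary(mask, center=(2.5, 2.5), search_radius=5.0)
    assert len(boundary) == 8
    # every boundary point is one of the ring cells, consecutive points adjacent
    steps = np.hypot(*np.diff(np.vstack([boundary, boundary[:1]]), axis=0).T)
    assert np.all(steps <= math.sqrt(2) + 1e-9)
    assert not any((x, y) == (2.5, 2.5) for x, y in boundary)  # center cell interior


def test_trace_disk_boundary_length_close_to_circumference():
    mask_arr, (cr, cc) = disk_mask(50)
    geom = GridGeometry(0.01, (0.0, 0.0), mask_arr.shape)
    mask = CanopyMask(mask_arr, geom)
    boundary = trace_boundary(mask, geom.center_of(cr, cc))
    closed = np.vstack([boundary, boundary[:1]])
    length = np.sum(np.hypot(*np.diff(closed, axis=0).T))
    assert length == pytest.approx(2 * np.pi * 0.50, rel=0.05)


def test_trace_empty_mask_raises_with_plant_id():
    mask = CanopyMask(np.zeros((10, 10), bool), GridGeometry(0.01, (0, 0), (10, 10)))
    with pytest.raises(EmptyCanopyError) as err:
        trace_boundary(mask, (0.05, 0.05), plant_id=42)
    assert err.value.plant_id == 42


def test_trace_picks_component_containing_center():
    values = np.zeros((11, 11))
    values[1:4, 1:4] = 1.0   # far component
    values[6:10, 6:10] = 1.0  # component at the center we ask for
    mask = binarize(make_grid(values, cell_size=1.0), threshold=0.5)
    boundary = trace_boundary(mask, center=(7.5, 7.5), search_radius=20.0)
    assert boundary[:, 0].min() >= 6.0 and boundary[:, 1].min() >= 6.0


# ------------------------------------------------------------- radial scan

def test_radial_scan_circle_yields_12_points_at_radius():
    mask_arr, (cr, cc) = disk_mask(100)
    geom = GridGeometry(0.01, (0.0, 0.0), mask_arr.shape)
    center = geom.center_of(cr, cc)
    boundary = trace_boundary(CanopyMask(mask_arr, geom), center)
    points = radial_scan(boundary, center, n_rays=12, ray_length=2.0)
    assert len(points) == 12
    d = np.hypot(points[:, 0] - center[0], points[:, 1] - center[1])
    assert np.all(np.abs(d - 1.0) <= 0.01 + 1e-9)  # within one cell of the radius
    # ordered by scan angle
    ang = np.mod(np.arctan2(points[:, 1] - center[1], points[:, 0] - center[0]), 2 * np.pi)
    assert np.all(np.diff(ang) > 0)


def test_radial_scan_too_few_intersections_is_degenerate():
    # small square far north-east of the center: only rays toward it intersect
    square = np.array([[1.5, 1.45], [1.6, 1.45], [1.6, 1.55], [1.5, 1.55]])
    with pytest.raises(DegenerateCanopyError) as err:
        radial_scan(square, center=(0.0, 0.0), n_rays=12, ray_length=2.0, plant_id=9)
    assert err.value.plant_id == 9
    assert err.value.n_points <= 2


def test_radial_scan_keeps_farthest_of_multiple_crossings():
    """A star-shaped outline crossing the eastward ray at 0.5 m and 0.9 m."""
    angles = np.linspace(np.radians(10), np.radians(350), 60)
    circle = np.column_stack([0.7 * np.cos(angles), 0.7 * np.sin(angles)])
    detour = np.array([[0.9, -0.02], [0.9, 0.02], [0.5, 0.02], [0.5, -0.02]])
    boundary = np.vstack([circle, detour])
    points = radial_scan(boundary, center=(0.0, 0.0), n_rays=12, ray_length=2.0)
    east = points[np.argmin(np.abs(np.arctan2(points[:, 1], points[:, 0])))]
    assert np.hypot(*east) == pytest.approx(0.9, abs=1e-6)


# ----------------------------------------------------------------- metrics

def test_polygon_metrics_unit_square():
    cp, ca = polygon_metrics([[0, 0], [1, 0], [1, 1], [0, 1]])
    assert cp == pytest.approx(4.0)
    assert ca == pytest.approx(1.0)


def test_polygon_metrics_regular_12gon_closed_forms():
    ang = np.arange(12) * np.pi / 6
    cp, ca = polygon_metrics(np.column_stack([np.cos(ang), np.sin(ang)]))
    assert cp == pytest.approx(24 * math.sin(math.radians(15)), abs=1e-12)
    assert ca == pytest.approx(3.0, abs=1e-12)


def test_polygon_metrics_matches_shoelace_oracle(rng):
    for _ in range(10):
        pts = rng.uniform(-2, 2, size=(7, 2))
        hull_ang = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
        pts = pts[np.argsort(hull_ang)]
        cp, ca = polygon_metrics(pts)
        cp_o, ca_o = shoelace(pts)
        assert cp == pytest.approx(cp_o)
        assert ca == pytest.approx(ca_o)


def test_polygon_metrics_needs_three_points():
    with pytest.raises(InvalidPolygonError):
        polygon_metrics([[0, 0], [1, 1]])


# -------------------------------------------------------------- phenotypes

def _polygon(vertices, plant_id=1):
    cp, ca = polygon_metrics(vertices)
    return CanopyPolygon(plant_id=plant_id, vertices=np.asarray(vertices, float), cp=cp, ca=ca)


def test_constant_chm_inside_polygon():
    chm = make_grid(np.full((30, 30), 1.3), cell_size=0.1)
    poly = _polygon([[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
    rec = extract_phenotypes(chm, poly)
    assert rec.ch_max == pytest.approx(1.3)
    assert rec.ch_mean == pytest.approx(1.3)


def test_single_peak_cell_sets_ch_max():
    values = np.full((30, 30), 0.5)
    values[15, 15] = 2.29
    chm = make_grid(values, cell_size=0.1)
    poly = _polygon([[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
    assert extract_phenotypes(chm, poly).ch_max == pytest.approx(2.29)


def test_ch_mean_matches_point_in_polygon_oracle(rng):
    values = rng.uniform(0, 2, size=(25, 25))
    chm = make_grid(values, cell_size=0.1)
    ang = np.arange(8) * np.pi / 4
    verts = np.column_stack([1.2 + 0.9 * np.cos(ang), 1.2 + 0.9 * np.sin(ang)])
    poly = _polygon(verts)
    rec = extract_phenotypes(chm, poly)
    import shapely

    sp = shapely.Polygon(verts)
    acc = [
        values[r, c]
        for r in range(25)
        for c in range(25)
        if sp.contains(shapely.Point(*chm.geom.center_of(r, c)))
    ]
    assert rec.ch_mean == pytest.approx(np.mean(acc))
    assert rec.ch_max == pytest.approx(np.max(acc))
    assert 0 <= rec.ch_mean <= rec.ch_max


def test_tiny_polygon_with_no_cell_centers_rejected():
    chm = make_grid(np.ones((10, 10)), cell_size=1.0)
    poly = _polygon([[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]])
    with pytest.raises(InvalidPolygonError):
        extract_phenotypes(chm, poly)


# -------------------------------------------------------------- end to end

def test_isolated_cylindrical_plant_end_to_end():
    """Noise-free circular canopy: CP within 5% of 2 pi R, CA within 5% of
    pi R^2, CH_max exact, vertices bounded by the scan geometry."""
    radius, height, cell = 0.8, 1.3, 0.01
    n = 260
    geom = GridGeometry(cell, (0.0, 0.0), (n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = n // 2
    values = np.where((xx - cx) ** 2 + (yy - cy) ** 2 <= (radius / cell) ** 2, height, 0.0)
    chm = make_grid(values, cell_size=cell)
    mask = binarize(smooth_chm(chm), threshold=0.10)
    center = geom.center_of(cy, cx)
    polygon, record = extract_plant(chm, mask, center, plant_id=1)
    assert record.status == "ok"
    assert record.cp == pytest.approx(2 * np.pi * radius, rel=0.05)
    # a 12-vertex simplification of a circle is bounded by the inscribed
    # 12-gon, whose area is 3 R^2 (= 0.955 pi R^2); compare against that
    assert record.ca == pytest.approx(3 * radius**2, rel=0.05)
    assert record.ca < np.pi * radius**2
    assert record.ch_max == pytest.approx(height, abs=1e-9)
    assert len(polygon.vertices) <= 12
    d = np.hypot(polygon.vertices[:, 0] - center[0], polygon.vertices[:, 1] - center[1])
    assert np.all(d <= 2.0)
    # simplified polygon cannot exceed the full traced outline's area (convex canopy)
    boundary = trace_boundary(mask, center)
    _, full_area = polygon_metrics(boundary)
    assert record.ca <= full_area + 1e-9
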