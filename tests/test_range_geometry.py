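import itertools

import numpy as np
import pytest
import shapely

from lagoshift.env_stack import GridSpec
from lagoshift.range_geometry import (
    DispersalSpec,
    buffer_km,
    build_clip_region,
    clip_map,
    future_buffer_distance,
    land_class_mask,
    minimum_convex_polygon,
)


def brute_force_hull(points):
    """O(n^3) convex hull: a point pair is a hull edge iff all other
    points lie on one side."""
    pts = [tuple(p) for p in points]
    hull_edges = []
    for a, b in itertools.permutations(pts, 2):
        cross = [
            (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            for p in pts if p not in (a, b)
        ]
        if all(c <= 1e-12 for c in cross):
            hull_edges.append((a, b))
    verts = {e[0] for e in hull_edges} | {e[1] for e in hull_edges}
    return verts


class TestLandClassMask:
    grid = GridSpec(n_rows=4, n_cols=4, cell_size=1.0, x_origin=0.0, y_origin=60.0)

    def test_all_classes_occupied_leaves_map_unchanged(self):
        lc = np.tile(np.array([0.0, 1.0, 2.0, 3.0]), (4, 1))
        suit = np.random.default_rng(0).random((4, 4))
        lon, lat = self.grid.cell_center([0, 0, 0, 0], [0, 1, 2, 3])
        out, occ = land_class_mask(suit, lc, self.grid, lon, lat)
        np.testing.assert_allclose(out, suit)
        assert occ == {0, 1, 2, 3}

    def test_unoccupied_classes_zeroed_per_cell_oracle(self):
        lc = np.tile(np.array([0.0, 1.0, 2.0, 3.0]), (4, 1))
        suit = np.ones((4, 4))
        lon, lat = self.grid.cell_center([0, 0], [0, 1])  # classes 0, 1 only
        out, occ = land_class_mask(suit, lc, self.grid, lon, lat)
        assert occ == {0, 1}
        for r in range(4):
            for c in range(4):
                assert out[r, c] == (1.0 if lc[r, c] in occ else 0.0)

    def test_record_on_nodata_ignored_with_warning(self):
        lc = np.zeros((4, 4))
        lc[0, 0] = np.nan
        suit = np.ones((4, 4))
        lon, lat = self.grid.cell_center([0, 1], [0, 1])
        with pytest.warns(UserWarning, match="nodata"):
            out, occ = land_class_mask(suit, lc, self.grid, lon, lat)
        assert occ == {0}


class TestMCP:
    def test_triangle(self):
        poly, degenerate = minimum_convex_polygon([0, 1, 0], [0, 0, 1])
        assert not degenerate
        assert poly.area == pytest.approx(0.5)

    def test_square_with_interior_point(self):
        poly, _ = minimum_convex_polygon([0, 1, 1, 0, 0.5], [0, 0, 1, 1, 0.5])
        assert poly.area == pytest.approx(1.0)
        assert len(poly.exterior.coords) == 5  # 4 corners + closing vertex

    def test_degenerate_collinear_flagged_and_buffered(self):
        poly, degenerate = minimum_convex_polygon([0, 1, 2], [0, 0, 0], fallback_buffer_deg=0.1)
        assert degenerate and poly.area > 0

    def test_matches_brute_force_hull_vertices(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pts = rng.random((50, 2)) * 10
            poly, _ = minimum_convex_polygon(pts[:, 0], pts[:, 1])
            got = {(round(x, 9), round(y, 9)) for x, y in poly.exterior.coords}
            want = {(round(x, 9), round(y, 9)) for x, y in brute_force_hull(pts)}
            assert got == want


class TestBufferKm:
    def test_zero_distance_identity(self):
        sq = shapely.box(0, 50, 1, 51)
        assert buffer_km(sq, 0.0).equals(sq)

    @pytest.mark.parametrize("lat", [0.0, 45.0, 70.0])
    def test_point_buffer_disc_area_any_latitude(self, lat):
        disc = buffer_km(shapely.Point(10.0, lat), 10.0, quad_segs=128)
        # area measured back in the same AEQD frame via a second projection
        from lagoshift.range_geometry import _aeqd_forward
        from shapely.ops import transform
        proj = transform(_aeqd_forward(10.0, lat), disc)
        assert proj.area == pytest.approx(np.pi * 100.0, rel=0.01)

    def test_buffers_nest(self):
        sq = shapely.box(0, 50, 1, 51)
        b5, b10 = buffer_km(sq, 5), buffer_km(sq, 10)
        assert b10.contains(b5)

    def test_antimeridian_crossing_raises_by_default(self):
        with pytest.raises(ValueError, match="antimeridian"):
            buffer_km(shapely.Point(179.9, 0.0), 100.0)


class TestFutureBufferDistance:
    disp = DispersalSpec("sp", 0.5)

    def test_elapsed_years_arithmetic(self):
        assert future_buffer_distance(self.disp, 2055) == pytest.approx(40.0)
        assert future_buffer_distance(DispersalSpec("sp", 1.0), 2025) == pytest.approx(50.0)

    def test_at_or_before_baseline_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert future_buffer_distance(self.disp, 1975) == 0.0


class TestClipMap:
    grid = GridSpec(n_rows=6, n_cols=6, cell_size=1.0, x_origin=0.0, y_origin=56.0)

    def test_full_cover_unchanged_empty_all_absence(self):
        vals = np.ones((6, 6))
        full = shapely.box(-1, 49, 7, 57)
        np.testing.assert_allclose(clip_map(vals, self.grid, full), vals)
        with pytest.warns(UserWarning, match="clip polygon"):
            out = clip_map(vals, self.grid, shapely.box(100, 0, 101, 1))
        assert (out == 0).all()

    def test_half_plane_per_cell_center_oracle(self):
        vals = np.ones((6, 6))
        half = shapely.box(-10, 0, 2.7, 90)  # cells with center lon < 2.7
        out = clip_map(vals, self.grid, half)
        for r in range(6):
            for c in range(6):
                lon, lat = self.grid.cell_center(r, c)
                assert out[r, c] == (1.0 if lon < 2.7 else 0.0)

    def test_clipping_never_adds_presences_and_nodata_survives(self):
        rng = np.random.default_rng(2)
        vals = (rng.random((6, 6)) > 0.5).astype(float)
        vals[0, 0] = np.nan
        out = clip_map(vals, self.grid, shapely.box(0, 50, 3, 53))
        assert np.isnan(out[0, 0])
        both = np.nan_to_num(out) > 0
        assert not (both & ~(np.nan_to_num(vals) > 0)).any()


class TestClipRegion:
    def test_future_regions_nest_over_time(self):
        rng = np.random.default_rng(3)
        lon = rng.uniform(0, 3, 30)
        lat = rng.uniform(50, 52, 30)
        cr = build_clip_region(lon, lat, DispersalSpec("sp", 1.0),
                               {"f2020s": 2025, "f2050s": 2055, "f2080s": 2085})
        r20 = cr.region(cr.future_buffer_km["f2020s"])
        r50 = cr.region(cr.future_buffer_km["f2050s"])
        r80 = cr.region(cr.future_buffer_km["f2080s"])
        assert r50.contains(r20) and r80.contains(r50)
        assert cr.future_buffer_km["f2020s"] >= cr.current_buffer_km >= 0
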