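import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, box

from beetlekern.landscape import (
    GeometryError,
    SamplingPoint,
    WoodRaster,
    buffer_wood_area,
    classify_edge_core,
    merge_field_points,
    rasterize_woodlands,
    source_distances,
)


def _pt(x, y, field="f1", site="s1"):
    return SamplingPoint("p1", field, site, x, y)


class TestRasterize:
    def test_exact_tiling_of_aligned_square(self):
        r = rasterize_woodlands([box(0, 0, 200, 200)], resolution=100.0)
        assert r.n_pixels == 4
        assert np.allclose(r.area_total, 10_000.0)

    def test_partial_pixel_areas_of_aligned_rectangle(self):
        r = rasterize_woodlands([box(0, 0, 150, 100)], resolution=100.0)
        assert sorted(r.area_total.tolist()) == [5000.0, 10000.0]

    def test_empty_polygon_set(self):
        assert rasterize_woodlands([]).n_pixels == 0

    def test_total_area_conserved_for_offset_rectangle(self):
        rect = box(37.5, 12.25, 612.5, 487.75)
        r = rasterize_woodlands([rect], resolution=100.0)
        assert r.area_total.sum() == pytest.approx(rect.area, rel=1e-6)

    def test_geographic_coordinates_rejected(self):
        wood_in_degrees = box(1.17, 48.95, 1.19, 48.97)
        with pytest.raises(GeometryError, match="projected"):
            rasterize_woodlands([wood_in_degrees])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(
            st.floats(-2000, 2000), st.floats(-2000, 2000),
            st.floats(30, 900), st.floats(30, 900),
        ),
        min_size=1, max_size=5,
    ))
    def test_conservation_over_random_rectangle_sets(self, rects):
        from shapely.ops import unary_union

        polys = [box(x, y, x + w, y + h) for x, y, w, h in rects]
        exact = unary_union(polys).area
        r = classify_edge_core(polys, band=100.0, resolution=100.0)
        assert r.area_total.sum() == pytest.approx(exact, rel=1e-4)


class TestEdgeCore:
    def test_disc_edge_and_core_areas(self):
        disc = Point(500, 500).buffer(150, quad_segs=256)
        r = classify_edge_core([disc], band=100.0, resolution=50.0)
        assert r.area_core.sum() == pytest.approx(math.pi * 50**2, rel=2e-2)
        assert r.area_edge.sum() == pytest.approx(
            math.pi * (150**2 - 50**2), rel=2e-2
        )

    def test_thin_rectangle_has_no_core(self):
        r = classify_edge_core([box(0, 0, 180, 500)], band=100.0)
        assert r.area_core.sum() == 0
        assert r.area_edge.sum() == pytest.approx(180 * 500, rel=1e-6)

    def test_zero_band_puts_everything_in_core(self):
        r = classify_edge_core([box(0, 0, 300, 300)], band=0.0)
        assert r.area_edge.sum() == 0
        assert r.area_core.sum() == pytest.approx(300 * 300, rel=1e-9)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            classify_edge_core([box(0, 0, 100, 100)], band=-1.0)

    def test_split_reproduces_plain_rasterization_totals(self):
        polys = [box(0, 0, 450, 380), box(600, 100, 900, 700)]
        plain = rasterize_woodlands(polys)
        split = classify_edge_core(polys, band=100.0)
        assert split.area_total.sum() == pytest.approx(
            plain.area_total.sum(), rel=1e-4
        )


class TestDistances:
    def test_point_at_pixel_center_has_zero_distance(self, tiny_raster):
        x, y = tiny_raster.x[0], tiny_raster.y[0]
        src = source_distances(_pt(x, y), tiny_raster)
        assert src.distance.min() == 0.0

    def test_three_four_five_triangle(self):
        r = WoodRaster(100.0, [350.0], [450.0], [0.0], [5000.0])
        src = source_distances(_pt(50.0, 50.0), r)
        assert src.distance.tolist() == [500.0]

    def test_cutoff_is_inclusive_boundary(self):
        r = WoodRaster(100.0, [50.0, 250.0], [50.0, 50.0], [0.0, 0.0],
                       [5000.0, 5000.0])
        near = source_distances(_pt(50.0 + 4999.0, 50.0), r, cutoff=5000.0)
        far = source_distances(_pt(50.0 + 5001.0, 50.0), r, cutoff=5000.0)
        assert 4999.0 in near.distance
        assert not (far.distance > 5000).any()
        assert len(far.distance) < 2

    def test_origin_edge_selects_edge_area_only(self, tiny_raster):
        pt = _pt(150.0, 100.0)
        all_src = source_distances(pt, tiny_raster, origin="area")
        edge_src = source_distances(pt, tiny_raster, origin="edge")
        assert edge_src.area.sum() <= all_src.area.sum()
        assert (edge_src.area > 0).all()

    def test_matches_brute_force_on_small_raster(self, tiny_raster, rng):
        pt = _pt(432.1, -87.6)
        src = source_distances(pt, tiny_raster, cutoff=1e9)
        brute = {
            (x, y): math.hypot(x - pt.x, y - pt.y)
            for x, y, a in zip(tiny_raster.x, tiny_raster.y, tiny_raster.area_total)
            if a > 0
        }
        got = {
            (tiny_raster.x[i], tiny_raster.y[i]): d
            for i, d in zip(src.index, src.distance)
        }
        assert got == brute

    def test_count_non_decreasing_in_cutoff(self, tiny_raster):
        pt = _pt(0.0, 0.0)
        counts = [
            len(source_distances(pt, tiny_raster, cutoff=c).distance)
            for c in (100, 500, 1000, 2000, 5000)
        ]
        assert counts == sorted(counts)


class TestBuffer:
    def test_no_pixels_in_radius(self, tiny_raster):
        assert buffer_wood_area(_pt(99000.0, 0.0), tiny_raster, 500.0) == 0.0

    def test_single_full_pixel(self):
        r = WoodRaster(100.0, [50.0], [50.0], [0.0], [10000.0])
        assert buffer_wood_area(_pt(0.0, 0.0), r, 500.0) == 10000.0

    def test_non_decreasing_in_radius(self, tiny_raster):
        pt = _pt(500.0, 500.0)
        areas = [
            buffer_wood_area(pt, tiny_raster, rad)
            for rad in np.linspace(50, 3000, 25)
        ]
        assert all(b >= a for a, b in zip(areas, areas[1:]))


class TestMergeAndIO:
    def test_two_point_barycenter(self):
        merged = merge_field_points([_pt(0, 0), _pt(100, 0)])
        assert (merged.x, merged.y) == (50.0, 0.0)

    def test_collinear_five_points(self):
        pts = [_pt(x, 7.0) for x in (0, 50, 100, 150, 200)]
        merged = merge_field_points(pts)
        assert (merged.x, merged.y) == (100.0, 7.0)

    def test_single_point_is_identity(self):
        p = _pt(3.0, 4.0)
        assert merge_field_points([p]) is p

    def test_mixed_fields_rejected(self):
        with pytest.raises(ValueError, match="multiple fields"):
            merge_field_points([_pt(0, 0, field="a"), _pt(1, 1, field="b")])

    def test_raster_csv_roundtrip(self, tiny_raster, tmp_path):
        path = tmp_path / "raster.csv"
        tiny_raster.write_csv(path)
        back = WoodRaster.read_csv(path)
        assert back.resolution == tiny_raster.resolution
        np.testing.assert_allclose(back.x, tiny_raster.x)
        np.testing.assert_allclose(back.area_edge, tiny_raster.area_edge)
        np.testing.assert_allclose(back.area_core, tiny_raster.area_core)

    def test_raster_rejects_overfull_pixel(self):
        with pytest.raises(ValueError, match="exceeds"):
            WoodRaster(100.0, [50.0], [50.0], [8000.0], [8000.0])
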