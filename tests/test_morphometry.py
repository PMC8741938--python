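"""Per-cell feature extraction: areas, minimum-area rectangle, ellipticity,
nucleus assignment."""

import math

import numpy as np
import pytest
import shapely.geometry

from ringmorph import morphometry as mm
from ringmorph.experiments import random_blob_mask, sweep_min_extent_area
from ringmorph.maskio import InstanceMasks


def _rect_mask(shape, rows, cols):
    mask = np.zeros(shape, bool)
    mask[rows, cols] = True
    return mask


class TestCellArea:
    def test_filled_rectangle_counts_pixels(self):
        mask = _rect_mask((30, 40), slice(3, 13), slice(5, 25))
        assert mm.cell_area(mask) == 200

    def test_single_pixel(self):
        mask = _rect_mask((5, 5), 2, 2)
        assert mm.cell_area(mask) == 1

    def test_rasterized_disk_close_to_analytic(self):
        yy, xx = np.mgrid[:60, :60]
        mask = (yy - 30.3) ** 2 + (xx - 29.6) ** 2 <= 20.0**2
        assert mm.cell_area(mask) == pytest.approx(math.pi * 400, rel=0.02)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mm.cell_area(np.zeros((4, 4), bool))


class TestMinAreaRect:
    def test_axis_aligned_rectangle_sides(self):
        mask = _rect_mask((30, 40), slice(3, 13), slice(5, 25))
        rect = mm.min_area_rect(mask)
        assert rect.side_long == pytest.approx(20, abs=1)
        assert rect.side_short == pytest.approx(10, abs=1)
        # never bigger than the axis-aligned bounding box footprint
        assert rect.area <= 200 + 1e-9

    def test_rotated_rectangle_recovers_area_and_angle(self):
        # rasterize a 10x20 rectangle rotated by 30 degrees
        theta = math.radians(30.0)
        yy, xx = np.mgrid[:50, :50]
        dy, dx = yy - 25.0, xx - 25.0
        u = dy * math.sin(theta) + dx * math.cos(theta)
        v = dy * math.cos(theta) - dx * math.sin(theta)
        mask = (np.abs(u) <= 10.0) & (np.abs(v) <= 5.0)
        rect = mm.min_area_rect(mask)
        assert rect.area == pytest.approx(21 * 11, rel=0.05)
        assert rect.angle_deg == pytest.approx(30.0, abs=3.0)

    def test_single_pixel_degenerate_convention(self):
        rect = mm.min_area_rect(_rect_mask((5, 5), 2, 2))
        assert (rect.side_long, rect.side_short) == (1.0, 1.0)

    def test_collinear_mask_short_side_one(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 2:9] = True
        rect = mm.min_area_rect(mask)
        assert rect.side_short == 1.0
        assert rect.side_long == pytest.approx(7.0)

    def test_never_exceeds_axis_aligned_bbox_on_random_blobs(self, rng):
        for _ in range(200):
            mask = random_blob_mask(rng)
            pts = np.argwhere(mask)
            aabb_extent = (
                (pts[:, 0].max() - pts[:, 0].min())
                * (pts[:, 1].max() - pts[:, 1].min())
            )
            rect = mm.min_area_rect(mask)
            assert rect.extent_area <= aabb_extent + 1e-9

    def test_matches_brute_force_sweep_on_random_convex_polygons(self, rng):
        from ringmorph.experiments import random_convex_points

        for _ in range(25):
            pts = random_convex_points(rng)
            rect = mm.min_area_rect(pts, points=True)
            sweep = sweep_min_extent_area(pts)
            # the grid sweep upper-bounds the optimum
            assert rect.extent_area <= sweep * (1 + 1e-6)

    def test_agrees_with_shapely_minimum_rotated_rectangle(self, rng):
        for _ in range(25):
            mask = random_blob_mask(rng)
            pts = np.argwhere(mask).astype(float)
            rect = mm.min_area_rect(mask)
            hull = shapely.geometry.MultiPoint(pts.tolist()).convex_hull
            ref = hull.minimum_rotated_rectangle.area
            assert rect.extent_area == pytest.approx(ref, rel=1e-9, abs=1e-9)


class TestEllipticity:
    def test_two_to_one_rectangle(self):
        mask = _rect_mask((30, 40), slice(3, 13), slice(5, 25))
        assert mm.ellipticity(mask) == pytest.approx(0.5)

    def test_disk_near_one(self):
        yy, xx = np.mgrid[:60, :60]
        mask = (yy - 30.0) ** 2 + (xx - 30.0) ** 2 <= 18.0**2
        assert mm.ellipticity(mask) == pytest.approx(1.0, abs=0.05)

    def test_single_pixel_is_one(self):
        assert mm.ellipticity(_rect_mask((5, 5), 2, 2)) == 1.0

    def test_invariance_under_translation_and_quarter_rotation(self, rng):
        mask = random_blob_mask(rng)
        base = mm.ellipticity(mask)
        assert mm.ellipticity(np.roll(mask, (7, -4), axis=(0, 1))) == pytest.approx(base, abs=1e-12)
        assert mm.ellipticity(np.rot90(mask)) == pytest.approx(base, abs=1e-9)


class TestAssignNuclei:
    def test_contained_nucleus_assigned(self, nested_square_masks):
        assert mm.assign_nuclei(nested_square_masks) == {1: 1}

    def test_largest_intersection_wins(self, overlap_masks):
        assert mm.assign_nuclei(overlap_masks) == {1: 2}

    def test_cell_without_nucleus_gets_none(self):
        cell = np.zeros((10, 10), np.uint16)
        cell[1:4, 1:4] = 1
        cell[6:9, 6:9] = 2
        nuc = np.zeros((10, 10), np.uint16)
        nuc[2, 2] = 1
        assert mm.assign_nuclei(InstanceMasks(cell, nuc)) == {1: 1, 2: None}

    def test_tie_breaks_to_smallest_nucleus_id(self):
        cell = np.zeros((8, 12), np.uint16)
        cell[2:6, 2:10] = 1
        nuc = np.zeros((8, 12), np.uint16)
        nuc[2:6, 2:4] = 2
        nuc[2:6, 6:8] = 1  # same 8-px overlap as nucleus 2
        assert mm.assign_nuclei(InstanceMasks(cell, nuc)) == {1: 1}


class TestExtractFeatures:
    def test_nested_square_fixture_exact_values(self, nested_square_masks):
        (rec,) = mm.extract_features(nested_square_masks)
        assert rec.sc == 81
        assert rec.sn == 9
        assert rec.ncr == pytest.approx(1 / 9)
        assert rec.ep == 1.0

    def test_empty_masks_empty_list(self):
        empty = InstanceMasks(np.zeros((5, 5), np.uint16), np.zeros((5, 5), np.uint16))
        assert mm.extract_features(empty) == []

    def test_no_nucleus_leaves_sn_ncr_null(self):
        cell = np.zeros((10, 10), np.uint16)
        cell[2:8, 2:8] = 1
        masks = InstanceMasks(cell, np.zeros_like(cell))
        (rec,) = mm.extract_features(masks)
        assert rec.sn is None and rec.ncr is None and rec.sc == 36

    def test_translation_leaves_all_features_unchanged(self, nested_square_masks):
        shifted = InstanceMasks(
            np.roll(nested_square_masks.cell_labels, (2, -1), axis=(0, 1)),
            np.roll(nested_square_masks.nucleus_labels, (2, -1), axis=(0, 1)),
        )
        a = mm.extract_features(nested_square_masks)[0]
        b = mm.extract_features(shifted)[0]
        assert (a.sc, a.sn, a.ep, a.ncr) == (b.sc, b.sn, b.ep, b.ncr)

    def test_frame_projection_keeps_values(self, nested_square_masks):
        records = mm.extract_features(nested_square_masks)
        df = mm.features_to_frame(records, slide_id="s1")
        assert df.loc[0, "sc"] == 81 and df.loc[0, "slide_id"] == "s1"

    def test_area_table_matches_full_extraction(self, nested_square_masks):
        df = mm.area_table(nested_square_masks)
        assert df.loc[0, "sc"] == 81 and df.loc[0, "sn"] == 9
        assert df.loc[0, "ncr"] == pytest.approx(1 / 9)
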