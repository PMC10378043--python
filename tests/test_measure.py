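import math

import numpy as np
import pytest

from ventrimetry.core_io import LabelVolume, VolumeGrid
from ventrimetry.measure import (
    PlanarMask,
    StageError,
    assign_laterality,
    binarize_segment,
    extract_components,
    measure_case,
    measure_width,
)
from ventrimetry.slice_select import select_reference_slice

from conftest import uniform_intensity_like


def _ref_and_components(labels):
    ref = select_reference_slice(labels)
    return ref, extract_components(labels, ref)


def _ellipse_mask(minor_vox, major_vox, angle_deg=0.0, shape=(80, 80)):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    t = math.radians(angle_deg)
    y, x = rr - shape[0] / 2 + 0.5, cc - shape[1] / 2 + 0.5
    u = x * math.cos(t) + y * math.sin(t)
    v = -x * math.sin(t) + y * math.cos(t)
    return (u / (major_vox / 2)) ** 2 + (v / (minor_vox / 2)) ** 2 <= 1.0


class TestExtractComponents:
    def test_phantom_has_three_components_with_csp(self, small_phantom):
        _, _, labels, truth = small_phantom
        _, comps = _ref_and_components(labels)
        assert len(comps) == truth.component_count_on_slice == 3
        assert comps[0].area_pixels >= comps[1].area_pixels >= comps[2].area_pixels

    def test_two_disjoint_squares(self):
        lab = np.zeros((20, 20, 3), dtype=np.int16)
        lab[2:7, 2:7, 1] = 4
        lab[10:15, 10:15, 1] = 4
        lab[0, 0, 1] = 6  # reference slice anchor
        vol = LabelVolume(lab, (0.5, 0.5, 0.5))
        _, comps = _ref_and_components(vol)
        assert [c.area_pixels for c in comps] == [25, 25]

    def test_corner_touching_squares_are_one_component(self):
        lab = np.zeros((20, 20, 3), dtype=np.int16)
        lab[2:7, 2:7, 1] = 4
        lab[7:12, 7:12, 1] = 4  # touches only diagonally at (6,6)/(7,7)
        lab[0, 0, 1] = 6
        vol = LabelVolume(lab, (0.5, 0.5, 0.5))
        _, comps = _ref_and_components(vol)
        assert len(comps) == 1

    def test_speckle_below_floor_dropped(self):
        lab = np.zeros((20, 20, 3), dtype=np.int16)
        lab[2:10, 2:10, 1] = 4
        lab[15, 15, 1] = 4  # single-pixel speck
        lab[0, 0, 1] = 6
        vol = LabelVolume(lab, (0.5, 0.5, 0.5))
        _, comps = _ref_and_components(vol)
        assert len(comps) == 1 and comps[0].area_pixels == 64

    def test_no_ventricle_on_slice_errors(self):
        lab = np.zeros((10, 10, 3), dtype=np.int16)
        lab[0, 0, 1] = 6
        vol = LabelVolume(lab, (0.5, 0.5, 0.5))
        ref = select_reference_slice(vol)
        with pytest.raises(StageError, match="no ventricle"):
            extract_components(vol, ref)


class TestLaterality:
    def test_phantom_sides_match_placement(self, small_phantom):
        _, _, labels, truth = small_phantom
        _, comps = _ref_and_components(labels)
        sides = assign_laterality(comps)
        # orientation RAS: rows grow toward subject right
        for side in ("right", "left"):
            expected = truth.ventricle_centers_vox[side]
            assert sides[side].centroid()[0] == pytest.approx(expected[0], abs=1.0)
        assert "csp" in sides

    def test_mirror_flip_swaps_sides(self, small_phantom):
        _, _, labels, _ = small_phantom
        flipped = LabelVolume(labels.labels[::-1].copy(), labels.spacing,
                              labels.orientation)
        sides = assign_laterality(_ref_and_components(labels)[1])
        sides_f = assign_laterality(_ref_and_components(flipped)[1])
        n = labels.shape[0] - 1
        assert sides_f["right"].centroid()[0] == pytest.approx(
            n - sides["left"].centroid()[0], abs=1e-6)

    def test_orientation_letter_controls_left_right(self, small_phantom):
        # same array, LAS instead of RAS: rows now grow toward subject left
        _, _, labels, _ = small_phantom
        relabeled = LabelVolume(labels.labels, labels.spacing, "LAS")
        sides_ras = assign_laterality(_ref_and_components(labels)[1])
        sides_las = assign_laterality(_ref_and_components(relabeled)[1])
        assert sides_ras["right"].centroid() == sides_las["left"].centroid()

    def test_single_component_errors(self):
        mask = PlanarMask(np.ones((8, 8), dtype=bool), (0.5, 0.5), 0)
        with pytest.raises(StageError, match="cannot separate"):
            assign_laterality([mask])

    def test_csp_must_lie_between_ventricles(self):
        big = np.zeros((30, 30), dtype=bool)
        a, b, off = big.copy(), big.copy(), big.copy()
        a[2:10, 10:20] = True
        b[20:28, 10:20] = True
        off[12:16, 2:5] = True  # between rows but found by centroid along rows
        comps = [PlanarMask(m, (0.5, 0.5), 0, "RA") for m in (a, b, off)]
        sides = assign_laterality(comps)
        assert sides["csp"].centroid()[0] == pytest.approx(13.5)


class TestBinarization:
    def test_uniform_intensity_keeps_everything(self):
        mask = PlanarMask(_ellipse_mask(10, 20), (0.5, 0.5), 0)
        seg = binarize_segment(uniform_intensity_like(mask.mask, 100.0), mask)
        np.testing.assert_array_equal(seg.mask.mask, mask.mask)
        assert seg.threshold == pytest.approx(100.0)
        assert not seg.plexus_detected

    def test_two_level_keeps_bright_half(self):
        mask2d = np.zeros((10, 10), dtype=bool)
        mask2d[2:8, 2:8] = True
        vol = uniform_intensity_like(mask2d, 0.0)
        vol.data[2:8, 2:5, 0] = 0.0
        vol.data[2:8, 5:8, 0] = 100.0
        seg = binarize_segment(vol, PlanarMask(mask2d, (0.5, 0.5), 0))
        assert seg.threshold == pytest.approx(50.0)
        assert seg.mask.mask.sum() == 18
        assert seg.mask.mask[:, 5:8].sum() == 18
        assert seg.plexus_detected  # the removed dark half is a real cluster

    def test_kept_mask_is_subset_of_component(self, asymmetric_phantom):
        _, grid, labels, _ = asymmetric_phantom
        _, comps = _ref_and_components(labels)
        for comp in comps[:2]:
            seg = binarize_segment(grid, comp)
            assert not (seg.mask.mask & ~comp.mask).any()
            assert not (seg.removed.mask & seg.mask.mask).any()

    def test_phantom_plexus_removed(self, asymmetric_phantom):
        _, grid, labels, truth = asymmetric_phantom
        _, comps = _ref_and_components(labels)
        sides = assign_laterality(comps)
        for side in ("right", "left"):
            seg = binarize_segment(grid, sides[side])
            i, j, _ = truth.plexus_centroids[side]
            assert not seg.mask.mask[int(round(i)), int(round(j))]
            assert seg.plexus_detected

    def test_idempotent_under_stored_threshold(self, asymmetric_phantom):
        _, grid, labels, _ = asymmetric_phantom
        ref, comps = _ref_and_components(labels)
        seg = binarize_segment(grid, comps[0])
        sl = grid.data[:, :, ref.index]
        assert (sl[seg.mask.mask] >= seg.threshold).all()

    def test_empty_result_falls_back_to_input(self):
        # a single pixel strictly below the (its own) mean cannot happen, but a
        # mask whose every pixel is NaN-free and equal keeps itself; force the
        # fallback with -inf trickery is not possible, so use a two-pixel mask
        # where the kept set equals the input (boundary >= keeps the max).
        mask2d = np.zeros((4, 4), dtype=bool)
        mask2d[1, 1] = mask2d[1, 2] = True
        vol = uniform_intensity_like(mask2d, 5.0)
        seg = binarize_segment(vol, PlanarMask(mask2d, (0.5, 0.5), 0))
        assert seg.mask.mask.sum() == 2 and not seg.plexus_detected


class TestMeasureWidth:
    def test_axis_aligned_ellipse_minrect(self):
        mask = PlanarMask(_ellipse_mask(16, 40), (0.5, 0.5), 0)
        m = measure_width(uniform_intensity_like(mask.mask, 100.0), mask)
        assert m.method == "minrect"
        assert m.width_mm == pytest.approx(8.0, abs=0.5)

    def test_rotated_ellipse_minrect(self):
        mask = PlanarMask(_ellipse_mask(16, 40, angle_deg=25), (0.5, 0.5), 0)
        m = measure_width(uniform_intensity_like(mask.mask, 100.0), mask)
        assert m.width_mm == pytest.approx(8.0, abs=1.0)

    def test_phantom_auto_uses_plexus_margin(self, asymmetric_phantom):
        spec, grid, labels, _ = asymmetric_phantom
        _, comps = _ref_and_components(labels)
        sides = assign_laterality(comps)
        m = measure_width(grid, sides["right"], mode="auto", side="right")
        assert m.plexus_detected and m.method == "plexus_margin"
        assert m.width_mm == pytest.approx(spec.right_width_mm, abs=1.0)
        assert m.width_mm <= m.rect.long_side_mm

    def test_plexus_margin_falls_back_without_cluster(self):
        mask = PlanarMask(_ellipse_mask(16, 40), (0.5, 0.5), 0)
        m = measure_width(uniform_intensity_like(mask.mask, 100.0), mask,
                          mode="plexus_margin")
        assert m.method == "minrect" and not m.plexus_detected

    @pytest.mark.parametrize("angle", [0, 30, 60, 89])
    def test_rotation_robustness(self, angle):
        mask = PlanarMask(_ellipse_mask(16, 40, angle_deg=angle), (0.5, 0.5), 0)
        m = measure_width(uniform_intensity_like(mask.mask, 100.0), mask)
        assert abs(m.width_mm - 8.0) <= 2 * 0.5


class TestMeasureCase:
    def test_symmetric_phantom(self, small_phantom):
        spec, grid, labels, truth = small_phantom
        right, left, ref = measure_case(grid, labels)
        assert ref.index == truth.reference_slice
        assert right.slice_index == left.slice_index == ref.index
        assert right.width_mm == pytest.approx(spec.right_width_mm, abs=1.0)
        assert left.width_mm == pytest.approx(spec.left_width_mm, abs=1.0)

    def test_asymmetric_phantom_lateralized(self, asymmetric_phantom):
        spec, grid, labels, _ = asymmetric_phantom
        right, left, _ = measure_case(grid, labels)
        assert right.width_mm == pytest.approx(12.0, abs=1.0)
        assert left.width_mm == pytest.approx(8.0, abs=1.0)

    def test_missing_ventricle_class_names_stage(self, small_phantom):
        _, grid, labels, _ = small_phantom
        no_vent = labels.labels.copy()
        no_vent[no_vent == 4] = 3
        stripped = LabelVolume(no_vent, labels.spacing, labels.orientation)
        with pytest.raises(StageError, match="extract_components"):
            measure_case(grid, stripped)

    def test_shape_mismatch_names_stage(self, small_phantom):
        _, grid, labels, _ = small_phantom
        small = VolumeGrid(grid.data[:-2], grid.spacing, grid.orientation)
        with pytest.raises(StageError, match="measure_case"):
            measure_case(small, labels)
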