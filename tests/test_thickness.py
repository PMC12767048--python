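"""Local thickness: digitization rule, oracle equivalence, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from vasculomap import (
    BinaryMask,
    apply_reliability_floor,
    diameter_distribution,
    local_thickness,
    make_region_set,
    make_scene,
    scene_union_mask,
    thickness_oracle,
)

from .conftest import horizontal_vessel, random_blob_mask


def mask_of(values, px=2.0):
    return BinaryMask(values=np.asarray(values, dtype=bool), pixel_size_um=px)


class TestDigitizationRule:
    def test_isolated_pixel_has_unit_diameter(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        t = local_thickness(mask_of(m))
        assert t.values[4, 4] == 2.0  # 1 pixel at 2 µm/pixel
        assert (t.values != 0).sum() == 1

    def test_one_pixel_line_is_one_everywhere(self):
        m = np.zeros((9, 20), bool)
        m[4, 2:18] = True
        t = local_thickness(mask_of(m, px=1.0))
        assert (t.values[m] == 1.0).all()

    def test_five_wide_strip_is_five_at_interior(self):
        m = np.zeros((20, 40), bool)
        m[8:13, :] = True
        t = local_thickness(mask_of(m, px=1.0))
        assert (t.values[8:13, 5:35] == 5.0).all()

    def test_filled_disk_center_reports_its_diameter(self):
        R = 9
        yy, xx = np.mgrid[-15:16, -15:16]
        m = yy**2 + xx**2 <= R**2
        t = local_thickness(mask_of(m, px=1.0))
        assert abs(t.values[15, 15] - 2 * R) <= 1.0

    def test_empty_mask_gives_all_zero_map(self):
        t = local_thickness(mask_of(np.zeros((10, 10))))
        assert not t.values.any()

    def test_support_equals_input_mask(self, rng):
        mask = random_blob_mask(rng)
        t = local_thickness(mask)
        assert np.array_equal(t.values > 0, mask.values)


class TestOracleEquivalence:
    def test_oracle_trivial_strips(self):
        m = np.zeros((12, 30), bool)
        m[5, 3:27] = True
        t = thickness_oracle(mask_of(m, px=1.0))
        assert (t.values[m] == 1.0).all()
        m5 = np.zeros((20, 30), bool)
        m5[6:11, :] = True
        t5 = thickness_oracle(mask_of(m5, px=1.0))
        assert (t5.values[8, 5:25] == 5.0).all()

    def test_fast_path_equals_oracle_on_random_blobs(self, rng):
        for _ in range(30):
            mask = random_blob_mask(rng, shape=(48, 48))
            fast = local_thickness(mask).values
            slow = thickness_oracle(mask).values
            assert np.array_equal(fast, slow)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fast_path_equals_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((24, 24)) > rng.uniform(0.3, 0.7)
        mask = mask_of(values)
        assert np.array_equal(local_thickness(mask).values,
                              thickness_oracle(mask).values)

    def test_oracle_refuses_oversized_masks(self):
        with pytest.raises(ValueError, match="at most"):
            thickness_oracle(mask_of(np.ones((65, 65))))


class TestProperties:
    def test_dilation_never_decreases_thickness(self, rng):
        mask = random_blob_mask(rng)
        t0 = local_thickness(mask).values
        dilated = BinaryMask(ndimage.binary_dilation(mask.values),
                             pixel_size_um=mask.pixel_size_um)
        t1 = local_thickness(dilated).values
        assert (t1[mask.values] >= t0[mask.values]).all()

    def test_calibration_linearity(self, rng):
        values = random_blob_mask(rng).values
        t1 = local_thickness(BinaryMask(values, 1.0)).values
        t3 = local_thickness(BinaryMask(values, 3.0)).values
        assert np.allclose(t3, 3.0 * t1)

    @pytest.mark.parametrize("width_um", [10.0, 18.0, 30.0, 42.0, 50.0])
    def test_straight_vessel_width_recovery(self, width_um):
        scene = make_scene(
            [horizontal_vessel(row_um=101.0, width_um=width_um)], (256, 256), 2.0
        )
        mask = scene_union_mask(scene)
        t = local_thickness(mask)
        interior = t.values[:, 60:196]  # away from capsule end caps
        vals = interior[interior > 0]
        assert abs(np.median(vals) - width_um) <= 2.0  # 1 pixel


class TestReliabilityFloor:
    def test_all_small_diameters_flagged(self):
        m = np.zeros((10, 30), bool)
        m[4:6, :] = True  # 2 px = 4 µm wide strip
        t = apply_reliability_floor(local_thickness(mask_of(m)), 5.0)
        assert t.unreliable[m].all()

    def test_large_diameters_unflagged_in_strip_interior(self):
        m = np.zeros((30, 60), bool)
        m[10:21, :] = True  # 11 px = 22 µm strip
        t = apply_reliability_floor(local_thickness(mask_of(m)), 5.0)
        # away from the strip ends (image border counts as background)
        assert not t.unreliable[:, 15:45].any()

    def test_flagged_fraction_matches_ground_truth_areas(self):
        widths = [4.0, 8.0, 12.0, 20.0]
        vessels = [
            horizontal_vessel(row_um=60.0 + 90.0 * i, width_um=w)
            for i, w in enumerate(widths)
        ]
        scene = make_scene(vessels, (256, 256), 2.0)
        mask = scene_union_mask(scene)
        t = apply_reliability_floor(local_thickness(mask), 5.0)
        flagged_frac = t.unreliable.sum() / mask.values.sum()
        areas = np.array([v.analytic_area_um2 for v in vessels])
        expected = areas[:2].sum() / areas.sum()  # the 4 and 8 µm vessels
        assert flagged_frac == pytest.approx(expected, abs=0.03)


class TestDiameterDistribution:
    def test_single_vessel_mode_in_its_width_bin(self):
        # 11 px wide on a pixel-center row: rasterizes to exactly 22 µm
        scene = make_scene([horizontal_vessel(width_um=22.0)], (256, 256), 2.0)
        regions = make_region_set((256, 256), {"cortex": (0, 256, 0, 256)}, 2.0)
        t = apply_reliability_floor(local_thickness(scene_union_mask(scene)))
        hist = diameter_distribution(t, regions, "cortex", bin_width_um=2.0)
        assert hist.relative_frequency.sum() == pytest.approx(1.0, abs=1e-9)
        mode_bin = np.argmax(hist.relative_frequency)
        lo, hi = hist.bin_edges[mode_bin], hist.bin_edges[mode_bin + 1]
        assert lo <= 22.0 <= hi

    def test_two_equal_area_vessels_give_two_equal_modes(self):
        # equal analytic capsule areas; odd pixel widths on pixel-center
        # rows so each vessel rasterizes to exactly its nominal width
        v2 = horizontal_vessel(row_um=221.0, x0_um=100.0, x1_um=280.0, width_um=30.0)
        l1 = (v2.analytic_area_um2 - np.pi * 7.0**2) / 14.0
        v1 = horizontal_vessel(row_um=81.0, x0_um=40.0, x1_um=40.0 + l1, width_um=14.0)
        assert v1.analytic_area_um2 == pytest.approx(v2.analytic_area_um2)
        scene = make_scene([v1, v2], (256, 256), 2.0)
        regions = make_region_set((256, 256), {"cortex": (0, 256, 0, 256)}, 2.0)
        t = apply_reliability_floor(local_thickness(scene_union_mask(scene)))
        hist = diameter_distribution(t, regions, "cortex", bin_width_um=2.0)
        freq_14 = hist.relative_frequency[
            np.searchsorted(hist.bin_edges, 14.0, side="right") - 1]
        freq_30 = hist.relative_frequency[
            np.searchsorted(hist.bin_edges, 30.0, side="right") - 1]
        assert freq_14 == pytest.approx(freq_30, rel=0.1)

    def test_no_eligible_pixels_rejected(self):
        regions = make_region_set((20, 20), {"cortex": (0, 20, 0, 20)}, 2.0)
        t = apply_reliability_floor(local_thickness(mask_of(np.zeros((20, 20)))))
        with pytest.raises(ValueError, match="no eligible"):
            diameter_distribution(t, regions, "cortex")
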