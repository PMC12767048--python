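"""Speed decoding, Poiseuille flow maps, regional CBF, distributions."""

import numpy as np
import pytest

from vasculomap import (
    FlowModelParams,
    IntensityMap,
    apply_reliability_floor,
    binarize,
    decode_speed,
    flow_distribution,
    flow_rate,
    flow_rate_map,
    local_thickness,
    make_region_set,
    make_scene,
    regional_cbf,
    render_density_map,
    render_directional_map,
    render_speed_map,
    scene_union_mask,
    speed_distribution,
)

from .conftest import horizontal_vessel


def speed_map_of(values, px=2.0):
    return IntensityMap(values=np.asarray(values, dtype=np.uint8),
                        pixel_size_um=px, modality="speed")


class TestDecodeSpeed:
    @pytest.mark.parametrize("grey,mm_s", [(255, 100.0), (0, 0.0), (51, 20.0)])
    def test_grey_divisor(self, grey, mm_s):
        decoded = decode_speed(speed_map_of([[grey]]))
        assert decoded.values[0, 0] == pytest.approx(mm_s, abs=1e-12)

    def test_rgb_input_rejected(self, simple_scene):
        with pytest.raises(ValueError, match="greyscale"):
            decode_speed(render_directional_map(simple_scene))

    def test_divisor_consistency_enforced(self):
        with pytest.raises(ValueError, match="grey_divisor"):
            FlowModelParams(grey_divisor=2.0)


class TestFlowRate:
    def test_unit_substitution(self):
        # v = 1 mm/s, r = 1 µm -> Q = pi * K
        assert flow_rate(1.0, 2.0) == pytest.approx(np.pi * 6e-8, rel=1e-12)

    def test_zero_speed_zero_flow(self):
        assert flow_rate(0.0, 30.0) == 0.0

    def test_worked_example(self):
        # v = 10 mm/s, d = 20 µm -> Q = 10 * pi * 100 * K = 6pi x 10^-5
        assert flow_rate(10.0, 20.0) == pytest.approx(6e-5 * np.pi, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            flow_rate(-1.0, 10.0)
        with pytest.raises(ValueError):
            flow_rate(1.0, -10.0)

    def test_unit_conversion_constant_from_dimensional_analysis(self):
        # (1 mm/s) * (1 µm^2) = 1e-3 m/s * 1e-12 m^2 = 1e-15 m^3/s
        m3_per_s = 1e-3 * 1e-12
        ml_per_min = m3_per_s * 1e6 * 60.0
        assert ml_per_min == pytest.approx(FlowModelParams().K, rel=1e-15)

    def test_linearity_in_v_quadratic_in_diameter(self):
        q = flow_rate(5.0, 10.0)
        assert flow_rate(10.0, 10.0) == pytest.approx(2 * q, rel=1e-12)
        assert flow_rate(5.0, 20.0) == pytest.approx(4 * q, rel=1e-12)


class TestFlowRateMap:
    @pytest.fixture
    def uniform_vessel(self):
        scene = make_scene(
            [horizontal_vessel(row_um=101.0, width_um=30.0, velocity=20.0)],
            (256, 256), 2.0,
        )
        mask = binarize(render_density_map(scene))
        tmap = apply_reliability_floor(local_thickness(mask))
        speed = decode_speed(render_speed_map(scene))
        return scene, mask, tmap, speed

    def test_uniform_vessel_interior_flow(self, uniform_vessel):
        scene, mask, tmap, speed = uniform_vessel
        fmap = flow_rate_map(speed, tmap)
        interior = (tmap.values == 30.0)
        interior[:, :40] = interior[:, 216:] = False  # clear of end caps
        expected = 20.0 * np.pi * 225.0 * 6e-8
        assert np.allclose(fmap.values[interior], expected, rtol=1e-12)

    def test_zero_speed_gives_zero_flow_map(self, uniform_vessel):
        scene, mask, tmap, _ = uniform_vessel
        zero = decode_speed(speed_map_of(np.zeros(scene.grid_shape)))
        assert not flow_rate_map(zero, tmap).values.any()

    def test_flagged_pixels_contribute_zero(self):
        scene = make_scene(
            [horizontal_vessel(row_um=101.0, width_um=7.0, velocity=20.0)],
            (256, 256), 2.0,
        )
        tmap = apply_reliability_floor(local_thickness(scene_union_mask(scene)))
        speed = decode_speed(render_speed_map(scene))
        assert not flow_rate_map(speed, tmap, apply_floor=True).values.any()
        assert flow_rate_map(speed, tmap, apply_floor=False).values.any()

    def test_shape_mismatch_rejected(self, uniform_vessel):
        _, _, tmap, _ = uniform_vessel
        small = decode_speed(speed_map_of(np.zeros((10, 10))))
        with pytest.raises(ValueError, match="shape mismatch"):
            flow_rate_map(small, tmap)

    def test_mixed_phantom_matches_ground_truth_recomputation(self):
        vessels = [
            horizontal_vessel(row_um=81.0, width_um=22.0, velocity=10.0),
            horizontal_vessel(row_um=241.0, width_um=34.0, velocity=40.0),
        ]
        scene = make_scene(vessels, (192, 256), 2.0)
        mask = scene_union_mask(scene)
        tmap = apply_reliability_floor(local_thickness(mask))
        speed = decode_speed(render_speed_map(scene))
        fmap = flow_rate_map(speed, tmap)
        for v in vessels:
            row = int(v.endpoints[0][0] / 2.0)
            interior = np.zeros(scene.grid_shape, bool)
            interior[row, 40:216] = True
            v_dec = round(v.velocity_mm_s * 2.55) / 2.55
            expected = v_dec * np.pi * (v.width_um / 2) ** 2 * 6e-8
            assert np.allclose(fmap.values[interior], expected, rtol=1e-12)


class TestRegionalCbf:
    def test_uniform_region_mean_is_that_q(self):
        scene = make_scene(
            [horizontal_vessel(row_um=101.0, width_um=30.0, velocity=20.0)],
            (256, 256), 2.0,
        )
        regions = make_region_set((256, 256), {"cortex": (0, 256, 0, 256)}, 2.0)
        mask = binarize(render_density_map(scene))
        tmap = apply_reliability_floor(local_thickness(mask))
        fmap = flow_rate_map(decode_speed(render_speed_map(scene)), tmap)
        q = regional_cbf(fmap, mask, regions, "cortex")
        assert q == pytest.approx(20.0 * np.pi * 225.0 * 6e-8, rel=0.10)

    def test_two_vessel_pixel_weighted_mean(self):
        vessels = [
            horizontal_vessel(row_um=81.0, width_um=22.0, velocity=10.0),
            horizontal_vessel(row_um=241.0, width_um=34.0, velocity=40.0),
        ]
        scene = make_scene(vessels, (192, 256), 2.0)
        regions = make_region_set((192, 256), {"cortex": (0, 192, 0, 256)}, 2.0)
        mask = scene_union_mask(scene)
        tmap = apply_reliability_floor(local_thickness(mask))
        fmap = flow_rate_map(decode_speed(render_speed_map(scene)), tmap)
        q = regional_cbf(fmap, mask, regions, "cortex")
        # hand computation: pixel-count-weighted mean of the two vessel Qs
        hand = fmap.values[fmap.eligible].mean()
        assert q == pytest.approx(hand, rel=1e-12)

    def test_empty_region_rejected(self):
        regions = make_region_set((20, 20), {"cortex": (0, 20, 0, 20)}, 2.0)
        from vasculomap import BinaryMask, FlowMap
        fmap = FlowMap(np.zeros((20, 20)), 2.0, eligible=np.zeros((20, 20), bool))
        mask = BinaryMask(np.zeros((20, 20), bool), 2.0)
        with pytest.raises(ValueError, match="no eligible"):
            regional_cbf(fmap, mask, regions, "cortex")


class TestDistributions:
    @pytest.fixture
    def two_speed_scene(self):
        vessels = [
            horizontal_vessel(row_um=81.0, x0_um=56.0, x1_um=456.0,
                              width_um=20.0, velocity=10.0),
            horizontal_vessel(row_um=241.0, x0_um=56.0, x1_um=456.0,
                              width_um=20.0, velocity=40.0),
        ]
        scene = make_scene(vessels, (192, 256), 2.0)
        regions = make_region_set((192, 256), {"cortex": (0, 192, 0, 256)}, 2.0)
        mask = scene_union_mask(scene)
        return scene, regions, mask

    def test_single_velocity_is_point_mass(self, simple_scene):
        regions = make_region_set((256, 256), {"cortex": (0, 256, 0, 256)}, 2.0)
        mask = scene_union_mask(simple_scene)
        speed = decode_speed(render_speed_map(simple_scene))
        hist = speed_distribution(speed, mask, regions, "cortex")
        assert hist.relative_frequency.max() == pytest.approx(1.0)

    def test_two_equal_area_velocities_split_evenly(self, two_speed_scene):
        scene, regions, mask = two_speed_scene
        speed = decode_speed(render_speed_map(scene))
        hist = speed_distribution(speed, mask, regions, "cortex")
        top_two = np.sort(hist.relative_frequency)[-2:]
        assert top_two.sum() == pytest.approx(1.0)
        assert top_two[0] == pytest.approx(top_two[1], abs=0.01)

    def test_flow_distribution_normalized(self, two_speed_scene):
        scene, regions, mask = two_speed_scene
        tmap = apply_reliability_floor(local_thickness(mask))
        fmap = flow_rate_map(decode_speed(render_speed_map(scene)), tmap)
        hist = flow_distribution(fmap, mask, regions, "cortex")
        assert hist.relative_frequency.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(hist.bin_edges) > 0)
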