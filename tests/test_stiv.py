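import math

import numpy as np
import pytest

from thermovitals import (
    FlowEstimate,
    LineROI,
    SpaceTimeImage,
    co2_volume,
    crop_exhalation,
    denoise_sti,
    enhance_contrast,
    estimate_flow,
    flow_volume,
    generate_mwir_phantom,
    generate_sti,
    mean_orientation,
    mean_subtract,
    per_hour,
    reslice,
    velocity_from_theta,
)
from thermovitals.synthetic import default_stiv_line

from conftest import make_stack
from sti_oracle import orientation_by_line_scan


def sti_of(values, sx=1.0, st=1.0):
    return SpaceTimeImage(np.asarray(values, dtype=float), sx=sx, st=st)


class TestReslice:
    def test_static_stack_gives_constant_sti(self):
        stack = make_stack(np.full((6, 10, 10), 4.0), pixel_scale=2e-3)
        sti = reslice(stack, LineROI(1, 1, 8, 8))
        np.testing.assert_allclose(sti.values, 4.0)
        assert sti.sx == 2e-3
        assert sti.st == pytest.approx(1 / 60)
        assert sti.n_time == 6

    def test_space_extent_is_floor_length_plus_one(self):
        stack = make_stack(np.zeros((2, 10, 20)))
        sti = reslice(stack, LineROI(5, 2, 5, 15.5))  # length 13.5 px
        assert sti.n_space == 14

    def test_line_outside_frame_rejected(self):
        stack = make_stack(np.zeros((2, 10, 10)))
        with pytest.raises(ValueError):
            reslice(stack, LineROI(0, 0, 12, 0))

    def test_missing_pixel_scale_falls_back_to_pixel_units(self):
        stack = make_stack(np.zeros((2, 10, 10)))
        sti = reslice(stack, LineROI(0, 0, 8, 0))
        assert sti.sx == 1.0
        assert "pixel units" in sti.provenance


class TestDenoise:
    def test_constant_sti_unchanged(self):
        out = denoise_sti(sti_of(np.full((4, 20), 2.0)), window_px=5)
        np.testing.assert_array_equal(out.values, 2.0)

    def test_single_pixel_impulse_removed(self):
        v = np.zeros((3, 40))
        v[1, 20] = 100.0
        out = denoise_sti(sti_of(v), window_px=15)
        assert out.values.max() == 0.0

    def test_step_edge_preserved_near_its_location(self):
        v = np.zeros((2, 60))
        v[:, 30:] = 1.0
        out = denoise_sti(sti_of(v), window_px=15)
        edge = np.flatnonzero(np.diff(out.values[0]) > 0.5)
        assert abs(edge[0] - 29) <= 8  # within half a window

    @pytest.mark.parametrize("window", [2, 1, 101])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            denoise_sti(sti_of(np.zeros((3, 50))), window_px=window)


class TestContrast:
    def test_constant_sti_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="constant"):
            out = enhance_contrast(sti_of(np.full((10, 10), 3.0)))
        np.testing.assert_array_equal(out.values, 3.0)

    def test_output_confined_to_unit_interval(self, rng):
        out = enhance_contrast(sti_of(rng.normal(size=(32, 32))))
        assert out.values.min() >= 0.0
        assert out.values.max() <= 1.0


class TestCropExhalation:
    def test_one_crop_per_window(self):
        sti = sti_of(np.zeros((120, 30)), st=1 / 60)
        windows = [(0.0, 0.5), (1.0, 1.5)]
        crops = crop_exhalation(sti, windows)
        assert len(crops) == 2
        assert all(c.n_time == 30 for c in crops)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            crop_exhalation(sti_of(np.zeros((60, 30)), st=1 / 60), [(1.0, 1.0)])


class TestOrientation:
    @pytest.mark.parametrize("slope", [1.0, 2.0])
    def test_known_slope_recovered_within_one_degree(self, slope):
        sti = generate_sti(slope, 120, 120)
        truth = math.degrees(math.atan(1 / slope))
        assert mean_orientation(sti) == pytest.approx(truth, abs=1.0)

    @pytest.mark.parametrize("slope", [0.5, 1.0, 2.0, 3.0])
    def test_agrees_with_line_scan_oracle_on_clean_sti(self, slope):
        sti = generate_sti(slope, 120, 120)
        assert mean_orientation(sti) == pytest.approx(
            orientation_by_line_scan(sti.values), abs=1.0
        )

    def test_invariant_to_affine_intensity_rescaling(self):
        sti = generate_sti(1.5, 100, 100)
        scaled = sti_of(3.7 * sti.values - 11.0)
        assert mean_orientation(sti_of(sti.values)) == pytest.approx(
            mean_orientation(scaled), abs=1e-9
        )

    def test_robust_to_mild_white_noise(self):
        clean = generate_sti(1.0, 120, 120)
        noisy = generate_sti(1.0, 120, 120, noise_sd=0.05, seed=5)  # 10% of contrast
        assert mean_orientation(noisy) == pytest.approx(
            mean_orientation(clean), abs=2.0
        )

    def test_constant_region_rejected(self):
        with pytest.raises(ValueError, match="gradient"):
            mean_orientation(sti_of(np.full((32, 32), 1.0)))


class TestVelocityConversions:
    def test_theta_45_with_equal_scales_gives_unit_velocity(self):
        assert velocity_from_theta(45.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_eq1_physical_units(self):
        assert velocity_from_theta(45.0, 2e-3, 1 / 60) == pytest.approx(0.12)

    def test_strictly_decreasing_in_theta(self):
        thetas = np.linspace(5, 85, 17)
        us = [velocity_from_theta(t, 1.0, 1.0) for t in thetas]
        assert np.all(np.diff(us) < 0)

    @pytest.mark.parametrize("theta", [0.0, 90.0, -5.0])
    def test_degenerate_angles_rejected(self, theta):
        with pytest.raises(ValueError):
            velocity_from_theta(theta, 1.0, 1.0)

    def test_flow_and_co2_identities(self):
        v = flow_volume(1.0, 7.18e-5)
        assert v == pytest.approx(7.18e-5)
        assert flow_volume(0.0, 1e-4) == 0.0
        assert flow_volume(2.0, 7.18e-5) == pytest.approx(2 * v)
        assert co2_volume(1.0) == pytest.approx(0.04)
        assert co2_volume(0.0) == 0.0
        assert per_hour(1 / 3600) == pytest.approx(1.0)
        assert per_hour(0.0) == 0.0

    def test_flow_estimate_identities_exact(self):
        est = FlowEstimate(theta_deg=50.0, u_m_per_s=1.1, area_m2=7.18e-5)
        assert est.v_m3_per_s == est.u_m_per_s * est.area_m2
        assert est.v_co2_m3_per_s == est.co2_fraction * est.v_m3_per_s


class TestEndToEnd:
    def test_phantom_velocity_recovered_within_ten_percent(self, stiv_cfg):
        stack, truth = generate_mwir_phantom(stiv_cfg)
        viz = mean_subtract(stack)
        flow = estimate_flow(
            viz,
            default_stiv_line(stiv_cfg),
            truth.exhalation_windows,
            area_m2=stiv_cfg.nostril_area_m2[0],
        )
        rel_err = abs(flow.u_m_per_s - truth.plume_velocity_m_per_s) / truth.plume_velocity_m_per_s
        assert rel_err <= 0.10
        assert len(flow.per_exhalation_u_m_per_s) == len(truth.exhalation_windows)
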