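import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import circular_diff_deg
from shgmetrics.errors import GeometryError, ParameterError
from shgmetrics.pshg import (fit_pshg, pitch_angle_from_ratio, pitch_map,
                             polarization_response, reconstruct_polar_response)
from shgmetrics.stacks import PolStack
from shgmetrics.synth import SyntheticScene, gen_pshg_stack


class TestPitchFormula:
    def test_b2_is_45_degrees(self):
        assert pitch_angle_from_ratio(2.0) == pytest.approx(45.0, abs=1e-12)

    def test_b1_reference_value(self):
        # arctan(sqrt(2)) evaluated at high precision
        assert pitch_angle_from_ratio(1.0) == pytest.approx(54.7356103172, abs=1e-9)

    def test_large_b_limit(self):
        assert pitch_angle_from_ratio(1e6) < 0.1

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ParameterError):
            pitch_angle_from_ratio(0.0)

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.01, max_value=100.0))
    def test_strictly_decreasing(self, b1, b2):
        if b1 == b2:
            return
        lo, hi = sorted((b1, b2))
        assert pitch_angle_from_ratio(lo) > pitch_angle_from_ratio(hi)


class TestFit:
    def test_round_trip_recovers_all_parameters(self):
        scene = SyntheticScene(b_true=1.5, phi_deg=77.0, amplitude=100.0,
                               offset=5.0, shape=(2, 2))
        fit = fit_pshg(gen_pshg_stack(scene), 0.0)
        assert fit.b_map[0, 0] == pytest.approx(1.5, rel=1e-8)
        assert circular_diff_deg(fit.phi_map[0, 0], 77.0) < 1e-6
        assert fit.amplitude_map[0, 0] == pytest.approx(100.0, rel=1e-7)
        assert fit.offset_map[0, 0] == pytest.approx(5.0, abs=1e-5)
        assert fit.r2_map[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_angle_uniform_pixel_masked_invalid(self):
        stack = PolStack(frames=np.full((18, 3, 3), 50.0),
                         angles_deg=np.arange(0, 180, 10.0))
        fit = fit_pshg(stack, 0.0)
        assert not fit.valid_mask.any()

    def test_too_few_angles_rejected(self):
        stack = PolStack(frames=np.ones((4, 2, 2)),
                         angles_deg=[0.0, 45.0, 90.0, 135.0])
        with pytest.raises(GeometryError):
            fit_pshg(stack, 0.0)

    def test_contrast_ratio_is_b_squared(self):
        # I(φ)/I(φ+90°) = b² for c = 0
        b, phi = 2.0, 40.0
        scene = SyntheticScene(b_true=b, phi_deg=phi, amplitude=10.0,
                               offset=0.0, shape=(1, 1))
        angles = np.array([40.0, 130.0])
        i_par = polarization_response(np.radians(phi), 10.0, np.radians(phi), b)
        i_perp = polarization_response(np.radians(phi + 90), 10.0, np.radians(phi), b)
        assert i_par / i_perp == pytest.approx(b ** 2, rel=1e-12)
        stack = gen_pshg_stack(scene, np.arange(0, 180, 10.0))
        idx_par = np.argmin(np.abs(stack.angles_deg - 40.0))
        idx_perp = np.argmin(np.abs(stack.angles_deg - 130.0))
        assert (stack.frames[idx_par, 0, 0] / stack.frames[idx_perp, 0, 0]
                == pytest.approx(b ** 2, rel=1e-12))

    def test_rotational_equivariance(self):
        base = dict(b_true=2.5, amplitude=80.0, shape=(1, 1))
        ref = fit_pshg(gen_pshg_stack(SyntheticScene(phi_deg=20.0, **base)), 0.0)
        rot = fit_pshg(gen_pshg_stack(SyntheticScene(phi_deg=95.0, **base)), 0.0)
        assert circular_diff_deg(rot.phi_map[0, 0] - ref.phi_map[0, 0], 75.0) < 1e-5
        assert rot.b_map[0, 0] == pytest.approx(ref.b_map[0, 0], rel=1e-8)

    def test_below_threshold_pixels_masked(self):
        scene = SyntheticScene(b_true=2.0, amplitude=100.0, shape=(2, 2))
        stack = gen_pshg_stack(scene)
        frames = stack.frames.copy()
        frames[:, 0, 0] = frames[:, 0, 0] / 1000.0   # one dim pixel
        dim = PolStack(frames=frames, angles_deg=stack.angles_deg)
        fit = fit_pshg(dim, min_mean_intensity=10.0)
        assert not fit.valid_mask[0, 0]
        assert fit.valid_mask[1, 1]


class TestPitchMap:
    def test_constant_b_map(self):
        fit = fit_pshg(gen_pshg_stack(SyntheticScene(b_true=2.0, shape=(3, 3))), 0.0)
        pm = pitch_map(fit)
        assert pm.mean_deg == pytest.approx(45.0, abs=1e-6)
        assert pm.sem_deg == pytest.approx(0.0, abs=1e-6)

    def test_mixed_b_map_mean(self):
        b_map = np.array([[1.0, 2.0]] * 2)
        fit = fit_pshg(gen_pshg_stack(
            SyntheticScene(b_true=b_map, phi_deg=30.0, shape=(2, 2))), 0.0)
        pm = pitch_map(fit)
        expected = (54.7356103172 + 45.0) / 2
        assert pm.mean_deg == pytest.approx(expected, abs=1e-4)

    def test_empty_mask_warns(self):
        stack = PolStack(frames=np.full((18, 2, 2), 7.0),
                         angles_deg=np.arange(0, 180, 10.0))
        with pytest.warns(UserWarning):
            pm = pitch_map(fit_pshg(stack, 0.0))
        assert np.isnan(pm.mean_deg) and pm.n_valid == 0


class TestReconstruction:
    def test_peak_at_fiber_orientation_and_periodicity(self):
        fit = fit_pshg(gen_pshg_stack(
            SyntheticScene(b_true=2.0, phi_deg=0.0, shape=(1, 1))), 0.0)
        dense = np.linspace(0.0, 360.0, 721)
        curve = reconstruct_polar_response(fit, dense)
        assert curve.max() == pytest.approx(1.0)
        assert curve[0] == pytest.approx(1.0, abs=1e-9)          # peak at θ=φ=0
        np.testing.assert_allclose(curve[:361], curve[360:], atol=1e-9)  # 180° period
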