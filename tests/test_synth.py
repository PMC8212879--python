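import numpy as np
import pytest

from shgmetrics.errors import ParameterError
from shgmetrics.synth import (SyntheticScene, default_angles, gen_chiral_pair,
                              gen_depth_series, gen_fiber_phantom,
                              gen_polarimetric_channels, gen_pshg_stack)


class TestPshgForwardModel:
    @pytest.mark.parametrize("theta_deg,expected", [
        (0.0, 400.0),     # A·b² = 100·4
        (90.0, 100.0),    # A·(0 + 1²)
        (45.0, 325.0),    # 100·(1 + (0.5 + 1)²)
    ])
    def test_known_values_b2_phi0(self, theta_deg, expected):
        scene = SyntheticScene(b_true=2.0, phi_deg=0.0, amplitude=100.0,
                               offset=0.0, shape=(3, 3))
        stack = gen_pshg_stack(scene, np.arange(0.0, 180.0, 45.0 / 4))
        idx = list(stack.angles_deg).index(theta_deg)
        np.testing.assert_allclose(stack.frames[idx], expected)

    def test_default_sweep_is_18_frames(self):
        stack = gen_pshg_stack(SyntheticScene(shape=(2, 2)))
        assert stack.n_angles == 18
        np.testing.assert_array_equal(stack.angles_deg, np.arange(0, 180, 10.0))

    def test_determinism(self):
        scene = dict(b_true=2.0, shape=(16, 16), noise="poisson", seed=9)
        a = gen_pshg_stack(SyntheticScene(**scene))
        b = gen_pshg_stack(SyntheticScene(**scene))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_invalid_b_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticScene(b_true=-1.0)


class TestPolarimetricChannels:
    def test_aligned_limit_beta1_perp_zero(self):
        par, perp = gen_polarimetric_channels(
            SyntheticScene(beta_true=1.0, shape=(4, 4)))
        np.testing.assert_allclose(perp.frames, 0.0, atol=1e-12)

    def test_random_limit_beta0_equal_channels(self):
        par, perp = gen_polarimetric_channels(
            SyntheticScene(beta_true=0.0, shape=(4, 4)))
        np.testing.assert_allclose(par.frames, perp.frames)

    def test_channel_split_solves_definition(self):
        # total T=90 with beta=0.5: IPar = T(1+2β)/(2+β) = 72, IPerp = 18
        par, perp = gen_polarimetric_channels(
            SyntheticScene(beta_true=0.5, shape=(4, 4)))
        t = par.frames + perp.frames
        np.testing.assert_allclose(
            (par.frames - perp.frames) / (par.frames + 2 * perp.frames), 0.5)
        one = t[0, 0, 0]
        np.testing.assert_allclose(par.frames[0, 0, 0], one * 72.0 / 90.0)
        np.testing.assert_allclose(perp.frames[0, 0, 0], one * 18.0 / 90.0)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticScene(beta_true=1.5)


class TestChiralPair:
    def test_epsilon_zero_identical(self):
        p = gen_chiral_pair(SyntheticScene(cd_epsilon=0.0, shape=(4, 4)))
        np.testing.assert_array_equal(p.lhcp, p.rhcp)

    def test_epsilon_one_base_100(self):
        p = gen_chiral_pair(SyntheticScene(cd_epsilon=1.0, amplitude=100.0,
                                           shape=(4, 4)))
        np.testing.assert_allclose(p.lhcp, 150.0)
        np.testing.assert_allclose(p.rhcp, 50.0)

    def test_epsilon_two_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticScene(cd_epsilon=2.0)


class TestDepthSeries:
    def test_flat_when_mu_zero(self):
        s = gen_depth_series(SyntheticScene(mu_atten_per_um=0.0, shape=(4, 4)))
        means = s.sections.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0])

    def test_closed_form_decay(self):
        s = gen_depth_series(SyntheticScene(mu_atten_per_um=0.01, shape=(4, 4)),
                             n_sections=9, z_step_um=10.0)
        ratio = s.sections[-1].mean() / s.sections[0].mean()
        np.testing.assert_allclose(ratio, np.exp(-0.8), rtol=1e-12)

    def test_too_few_sections_rejected(self):
        with pytest.raises(ParameterError):
            gen_depth_series(SyntheticScene(shape=(4, 4)), n_sections=2)


class TestFiberPhantom:
    def test_straight_segment_truth(self):
        scene = SyntheticScene(fiber_spec=[(50.0, 2.0, 1.0, 30.0)],
                               shape=(128, 128), pixel_size_um=0.5, seed=1)
        _, truth = gen_fiber_phantom(scene)
        assert truth[0]["straightness"] == pytest.approx(1.0, abs=1e-9)
        assert truth[0]["length_um"] == pytest.approx(50.0, rel=1e-6)

    def test_semicircle_truth_is_two_over_pi(self):
        scene = SyntheticScene(fiber_spec=[(50.0, 2.0, 2 / np.pi, 0.0)],
                               shape=(128, 128), pixel_size_um=0.5, seed=1)
        _, truth = gen_fiber_phantom(scene)
        assert truth[0]["straightness"] == pytest.approx(2 / np.pi, abs=1e-4)

    def test_binary_cross_section_thickness(self):
        # 4 px wide horizontal fiber: un-blurred band is 4 px thick on average
        scene = SyntheticScene(fiber_spec=[(40.0, 4 * 0.5, 1.0, 0.0)],
                               shape=(96, 96), pixel_size_um=0.5, seed=2)
        img, _ = gen_fiber_phantom(scene, blur_sigma_px=1e-6)
        cols = np.nonzero(img.max(axis=0) > 0.5 * img.max())[0]
        inner = cols[5:-5]
        thickness = (img[:, inner] > 0.5 * img.max()).sum(axis=0)
        assert abs(thickness.mean() - 4.0) <= 1.0

    def test_poisson_noise_preserves_mean(self):
        scene = SyntheticScene(cd_epsilon=0.0, amplitude=1000.0, noise="poisson",
                               shape=(400, 400), seed=8)
        pair = gen_chiral_pair(scene)
        n = pair.lhcp.size
        se = np.sqrt(1000.0 / n)
        assert abs(pair.lhcp.mean() - 1000.0) < 4 * se
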