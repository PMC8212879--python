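import numpy as np
import pytest

from shgmetrics.errors import PlacementError
from shgmetrics.fibers import FiberRecord, extract_fibers, fiber_summary
from shgmetrics.synth import SyntheticScene, gen_fiber_phantom

PX = 0.5  # µm/pixel for all phantoms here


def _phantom(spec, seed, shape=(128, 128), noise="none", amplitude=1000.0):
    scene = SyntheticScene(fiber_spec=spec, shape=shape, pixel_size_um=PX,
                           amplitude=amplitude, noise=noise, seed=seed)
    return gen_fiber_phantom(scene)


class TestExtraction:
    def test_single_straight_fiber(self):
        img, truth = _phantom([(50.0, 2.0, 1.0, 20.0)], seed=3)
        recs = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
        assert len(recs) == 1
        r = recs[0]
        assert r.straightness >= 0.99
        assert r.length_um == pytest.approx(50.0, rel=0.05)
        assert abs(r.width_um - 2.0) <= PX   # within one pixel

    def test_semicircular_arc_straightness(self):
        img, truth = _phantom([(50.0, 2.0, 2 / np.pi, 0.0)], seed=5)
        recs = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
        assert len(recs) == 1
        assert abs(recs[0].straightness - 2 / np.pi) <= 0.03

    def test_blank_image_gives_empty_list(self):
        assert extract_fibers(np.zeros((64, 64)), PX) == []

    def test_rotation_invariance_within_two_percent(self):
        metrics = {}
        for ang in (0.0, 90.0):
            img, _ = _phantom([(50.0, 2.0, 1.0, ang)], seed=7)
            (rec,) = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
            metrics[ang] = rec
        assert metrics[90.0].length_um == pytest.approx(
            metrics[0.0].length_um, rel=0.02)
        assert metrics[90.0].width_um == pytest.approx(
            metrics[0.0].width_um, rel=0.02)
        assert metrics[90.0].straightness == pytest.approx(
            metrics[0.0].straightness, abs=0.02)

    def test_scale_covariance_of_pixel_size(self):
        img, _ = _phantom([(50.0, 2.0, 1.0, 30.0)], seed=9)
        (a,) = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
        (b,) = extract_fibers(img, pixel_size_um=2 * PX, min_length_um=20.0)
        assert b.length_um == pytest.approx(2 * a.length_um, rel=1e-12)
        assert b.width_um == pytest.approx(2 * a.width_um, rel=1e-12)
        assert b.straightness == pytest.approx(a.straightness, abs=1e-12)

    def test_straightness_never_exceeds_one(self):
        img, _ = _phantom(
            [(40.0, 2.0, 1.0, 10.0), (30.0, 2.5, 0.8, 120.0),
             (25.0, 1.5, 0.9, 60.0, "walk")],
            seed=11, shape=(192, 192), noise="poisson", amplitude=800.0)
        recs = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
        assert recs
        assert all(0.0 < r.straightness <= 1.0 for r in recs)

    def test_multi_fiber_summary_tracks_ground_truth(self):
        spec = [(35 + 5 * (i % 3), 2.0 + 0.5 * (i % 2),
                 [1.0, 0.85, 0.92][i % 3], 15.0 * i) for i in range(8)]
        img, truth = _phantom(spec, seed=11, shape=(300, 300),
                              noise="poisson", amplitude=800.0)
        recs = extract_fibers(img, pixel_size_um=PX, min_length_um=10.0)
        summ = fiber_summary(recs)
        assert summ["n_fibers"] == len(truth)
        t_len = np.mean([t["length_um"] for t in truth])
        t_str = np.mean([t["straightness"] for t in truth])
        assert summ["length_um_mean"] == pytest.approx(t_len, rel=0.10)
        assert summ["straightness_mean"] == pytest.approx(t_str, abs=0.05)

    def test_oversized_fiber_rejected(self):
        with pytest.raises(PlacementError):
            _phantom([(200.0, 2.0, 1.0, 0.0)], seed=1, shape=(64, 64))


class TestSummary:
    def test_mean_and_sem_arithmetic(self):
        recs = [FiberRecord(np.zeros((2, 2)), 40.0, 2.0, 1.0),
                FiberRecord(np.zeros((2, 2)), 60.0, 2.0, 1.0)]
        s = fiber_summary(recs)
        assert s["length_um_mean"] == 50.0
        assert s["length_um_sem"] == pytest.approx(10.0)

    def test_single_fiber_sem_absent(self):
        s = fiber_summary([FiberRecord(np.zeros((2, 2)), 40.0, 2.0, 1.0)])
        assert np.isnan(s["length_um_sem"])

    def test_empty_summary(self):
        s = fiber_summary([])
        assert s["n_fibers"] == 0 and np.isnan(s["straightness_mean"])
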