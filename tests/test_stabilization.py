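"""Detection, tracking, robust similarity estimation, warping, pipeline."""

import math

import numpy as np
import pytest
from skimage.measure import ransac as sk_ransac
from skimage.transform import SimilarityTransform as SkSimilarity

from capstab import (
    DETECTORS,
    MatchedPairs,
    SceneSpec,
    SimilarityTransform,
    StabilizerParams,
    TremorConfig,
    about_center,
    detect_keypoints,
    estimate_transform,
    identity,
    perturb_sequence,
    render_frame,
    render_sequence,
    stabilize,
    to_matrix,
    track_keypoints,
    warp_frame,
)
from capstab.metrics import recovered_perturbations, rms_errors


class TestDetect:
    @pytest.mark.parametrize("method", DETECTORS)
    def test_constant_frame_empty(self, method):
        flat = np.full((120, 160), 128, np.uint8)
        assert len(detect_keypoints(flat, method)) == 0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            detect_keypoints(np.zeros((50, 50), np.uint8), "surf")

    def test_gftt_square_corners(self):
        img = np.zeros((120, 120), np.uint8)
        img[30:90, 30:90] = 255
        kps = detect_keypoints(img, "gftt", max_keypoints=10)
        corners = np.array([[30, 30], [89, 30], [30, 89], [89, 89]], float)
        found = kps.points[:4]
        for c in corners:
            assert np.min(np.hypot(*(found - c).T)) <= 2.0

    @pytest.mark.parametrize("method", DETECTORS)
    def test_synthetic_scene_keypoint_budget(self, method, small_frames):
        kps = detect_keypoints(small_frames[0], method, max_keypoints=200)
        assert 0 < len(kps) <= 200
        assert np.all(np.diff(kps.responses) <= 1e-12)  # descending
        h, w = small_frames[0].shape
        assert np.all((kps.points[:, 0] >= 0) & (kps.points[:, 0] <= w - 1))
        assert np.all((kps.points[:, 1] >= 0) & (kps.points[:, 1] <= h - 1))


class TestTracking:
    def test_zero_motion(self, small_frames):
        f = small_frames[0]
        kps = detect_keypoints(f, "gftt")
        pairs = track_keypoints(f, f, kps)
        assert pairs.valid_count > 0
        d = np.hypot(*(pairs.curr_pts - pairs.prev_pts).T)
        assert np.all(d < 0.5)

    def test_known_integer_shift(self, small_frames):
        f = small_frames[0]
        shifted = warp_frame(f, to_matrix(SimilarityTransform(1, 0, 5, 3)))
        kps = detect_keypoints(f, "gftt")
        pairs = track_keypoints(f, shifted, kps)
        assert pairs.valid_count >= 10
        flow = pairs.curr_pts - pairs.prev_pts
        med = np.median(flow, axis=0)
        assert med[0] == pytest.approx(5.0, abs=0.3)
        assert med[1] == pytest.approx(3.0, abs=0.3)

    def test_unrelated_noise_negative_control(self, small_frames):
        rng = np.random.default_rng(0)
        noise = (rng.random(small_frames[0].shape) * 255).astype(np.uint8)
        kps = detect_keypoints(small_frames[0], "gftt")
        pairs = track_keypoints(small_frames[0], noise, kps)
        assert pairs.valid_count <= 0.05 * len(kps)


class TestEstimateTransform:
    @staticmethod
    def _pairs_from(t, n=60, seed=0):
        rng = np.random.default_rng(seed)
        src = rng.uniform([0, 0], [320, 240], size=(n, 2))
        return src, t.apply(src)

    def test_noiseless_exact_recovery(self):
        t = SimilarityTransform(1.02, 0.03, 4.5, -2.25)
        src, dst = self._pairs_from(t)
        res = estimate_transform(MatchedPairs(src, dst))
        assert not res.failed
        assert res.transform.is_close(t, tol=1e-6)

    def test_robust_to_20pct_outliers(self):
        t = SimilarityTransform(1.0, math.radians(1.0), 3.0, -2.0)
        src, dst = self._pairs_from(t, n=100, seed=1)
        rng = np.random.default_rng(2)
        bad = rng.choice(100, size=20, replace=False)
        dst[bad] = rng.uniform([0, 0], [320, 240], size=(20, 2))
        res = estimate_transform(MatchedPairs(src, dst), seed=3)
        assert not res.failed
        assert res.transform.dx == pytest.approx(t.dx, abs=0.5)
        assert res.transform.dy == pytest.approx(t.dy, abs=0.5)
        assert math.degrees(abs(res.transform.theta - t.theta)) < 0.2

    def test_underdetermined_returns_identity_sentinel(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0]])
        res = estimate_transform(MatchedPairs(src, src + 5))
        assert res.failed
        assert res.transform.is_close(identity(), tol=0.0)

    def test_agrees_with_skimage_ransac(self):
        # independent robust-estimation route on a noisy, outlier-laced fixture
        t = SimilarityTransform(0.99, -0.02, -3.0, 4.0)
        src, dst = self._pairs_from(t, n=150, seed=5)
        rng = np.random.default_rng(6)
        dst += rng.normal(0, 0.3, size=dst.shape)
        bad = rng.choice(150, size=30, replace=False)
        dst[bad] = rng.uniform([0, 0], [320, 240], size=(30, 2))
        ours = estimate_transform(MatchedPairs(src, dst), seed=7).transform
        model, _ = sk_ransac(
            (src, dst), SkSimilarity, min_samples=2, residual_threshold=3.0,
            max_trials=2000, rng=7,
        )
        assert ours.dx == pytest.approx(model.translation[0], abs=0.2)
        assert ours.dy == pytest.approx(model.translation[1], abs=0.2)
        assert ours.theta == pytest.approx(model.rotation, abs=1e-3)
        assert ours.s == pytest.approx(model.scale, abs=1e-3)


class TestWarp:
    def test_identity_bitwise(self, small_frames):
        out = warp_frame(small_frames[0], np.array([[1.0, 0, 0], [0, 1, 0]]))
        assert np.array_equal(out, small_frames[0])

    def test_integer_shift_roundtrip_interior(self, small_frames):
        f = small_frames[0]
        fwd = warp_frame(f, to_matrix(SimilarityTransform(1, 0, 7, -4)))
        back = warp_frame(fwd, to_matrix(SimilarityTransform(1, 0, -7, 4)))
        m = 12  # padding margin
        assert np.array_equal(back[m:-m, m:-m], f[m:-m, m:-m])

    def test_half_turn_of_symmetric_pattern(self):
        yy, xx = np.mgrid[0:101, 0:101]
        pattern = (((xx - 50) ** 2 + (yy - 50) ** 2) % 97).astype(np.uint8)
        m = about_center(SimilarityTransform(1, math.pi, 0, 0), 101, 101)
        out = warp_frame(pattern, m)
        assert np.array_equal(out[5:-5, 5:-5], pattern[5:-5, 5:-5])

    def test_rejects_nonfinite(self, small_frames):
        with pytest.raises(ValueError):
            warp_frame(small_frames[0], np.array([[np.nan, 0, 0], [0, 1, 0]]))


class TestStabilize:
    def test_static_sequence_estimates_null_motion(self):
        spec = SceneSpec(width=320, height=240, n_rbc=0, seed=3)
        frames = render_sequence(spec, 5)
        _, path, flags = stabilize(frames, "gftt")
        assert not any(flags)
        for t in path.inter:
            assert abs(t.dx) < 0.5 and abs(t.dy) < 0.5
            assert math.degrees(abs(t.theta)) < 0.1

    def test_two_frame_sequence(self, small_frames):
        out, path, flags = stabilize(small_frames[:2], "gftt")
        assert len(out) == 2
        assert out[0] is small_frames[0]
        assert len(path.inter) == 1 and len(flags) == 1

    def test_featureless_video_degrades_gracefully(self):
        frames = [np.full((80, 100), 100, np.uint8) for _ in range(4)]
        out, path, flags = stabilize(frames, "gftt")
        assert all(flags)
        assert all(t.is_close(identity(), tol=0.0) for t in path.inter)
        assert all(np.array_equal(a, b) for a, b in zip(out, frames))

    def test_recovers_known_perturbations(self, small_frames):
        cfg = TremorConfig(0.005, 0.005, 0.005, seed=11)
        perturbed, truth = perturb_sequence(small_frames, cfg)
        _, path, flags = stabilize(perturbed, "gftt")
        assert not any(flags)
        h, w = small_frames[0].shape
        rec = recovered_perturbations(path, w, h)
        rdx, rdy, rrot = rms_errors(rec, truth, w, h)
        assert rdx <= 1.0 and rdy <= 1.0 and rrot <= 0.5

    def test_idempotence(self, small_frames):
        cfg = TremorConfig(0.0075, 0.0075, 0.0075, seed=12)
        perturbed, _ = perturb_sequence(small_frames, cfg)
        once, _, _ = stabilize(perturbed, "gftt")
        _, path2, _ = stabilize(once, "gftt")
        for c in path2.cumulative:
            assert np.hypot(c.dx, c.dy) < 1.0

    def test_detectors_are_interchangeable(self, small_frames):
        cfg = TremorConfig(0.01, 0.01, 0.01, seed=13)
        perturbed, _ = perturb_sequence(small_frames, cfg)
        shapes = set()
        for m in DETECTORS:
            _, path, flags = stabilize(perturbed, m, StabilizerParams(seed=1))
            shapes.add((len(path.inter), len(path.cumulative), len(flags)))
        assert len(shapes) == 1
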