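"""Keypoint-based video stabilization.

For every consecutive frame pair the pipeline (i) detects keypoints on the
earlier frame (SIFT, ORB or GFTT — re-detected per frame, no long-term
tracks), (ii) tracks them into the later frame with sparse pyramidal
Lucas–Kanade flow and prunes failures with a forward–backward check,
(iii) fits a 4-DOF similarity transform to the surviving correspondences
with RANSAC + least squares, and (iv) aligns every frame to frame 0 by
chaining the inverse transforms cumulatively and warping with bilinear
interpolation and reflection padding.

Frames too poor to yield an estimate contribute an identity link and are
flagged rather than dropped, so the cumulative chain always matches the
frame count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import ORB, SIFT, corner_peaks, corner_shi_tomasi

from .flow import FlowParams, track_points
from .geometry import MotionPath, SimilarityTransform, identity, to_matrix
from .warping import warp_frame

__all__ = [
    "KeypointSet",
    "MatchedPairs",
    "StabilizerParams",
    "detect_keypoints",
    "track_keypoints",
    "estimate_transform",
    "estimate_motion_path",
    "stabilize",
    "warp_frame",
    "DETECTORS",
]

logger = logging.getLogger(__name__)

DETECTORS = ("sift", "orb", "gftt")


@dataclass
class KeypointSet:
    """Detected keypoints: (x, y) subpixel positions, strongest first."""

    points: np.ndarray          # (n, 2) float64, (x, y)
    responses: np.ndarray       # (n,) detector score, descending
    method: str

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MatchedPairs:
    """Validated correspondences between two consecutive frames."""

    prev_pts: np.ndarray        # (n, 2) float64
    curr_pts: np.ndarray        # (n, 2) float64

    @property
    def valid_count(self) -> int:
        return len(self.prev_pts)


@dataclass(frozen=True)
class StabilizerParams:
    max_keypoints: int = 200
    flow: FlowParams = field(default_factory=FlowParams)
    fb_threshold_px: float = 1.0    # forward-backward reprojection gate
    min_pairs: int = 3
    ransac_threshold_px: float = 3.0
    ransac_confidence: float = 0.99
    ransac_max_iter: int = 2000
    seed: int = 0


def _as_float(frame: np.ndarray) -> np.ndarray:
    return np.asarray(frame, dtype=np.float64)


def _shi_tomasi_at(response: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(
        response, [pts_xy[:, 1], pts_xy[:, 0]], order=1, mode="nearest"
    )


def detect_keypoints(
    frame: np.ndarray, method: str, max_keypoints: int = 200
) -> KeypointSet:
    """Detect at most ``max_keypoints`` strongest keypoints.

    No pre-processing (contrast enhancement, denoising) is applied before
    detection; the detectors see the raw 8-bit frame.  An empty detection
    (e.g. a constant frame) returns an empty set, not an error.

    Notes
    -----
    The SIFT implementation used here does not expose a per-keypoint
    contrast response, so SIFT keypoints are ranked by the Shi–Tomasi
    corner measure sampled at their positions; this only affects which
    detections survive truncation to ``max_keypoints``.
    """
    method = method.lower()
    if method not in DETECTORS:
        raise ValueError(f"unknown detector {method!r}; expected one of {DETECTORS}")
    img = _as_float(frame)
    empty = KeypointSet(
        points=np.empty((0, 2)), responses=np.empty(0), method=method
    )
    if img.std() == 0:
        return empty

    if method == "gftt":
        resp = corner_shi_tomasi(img)
        peaks = corner_peaks(
            resp, min_distance=7, threshold_rel=0.01, num_peaks=max_keypoints
        )
        if len(peaks) == 0:
            return empty
        pts = peaks[:, ::-1].astype(np.float64)  # (row, col) -> (x, y)
        scores = resp[peaks[:, 0], peaks[:, 1]]
    elif method == "orb":
        det = ORB(n_keypoints=max_keypoints)
        try:
            det.detect(img)
        except (RuntimeError, ValueError):
            return empty
        if det.keypoints is None or len(det.keypoints) == 0:
            return empty
        pts = det.keypoints[:, ::-1].astype(np.float64)
        scores = np.asarray(det.responses, dtype=np.float64)
    else:  # sift
        # initial 2x upsampling adds ~15x cost for sub-pixel blobs smaller
        # than one pixel; capillary structures are several pixels wide, so
        # detection starts at native resolution
        det = SIFT(upsampling=1)
        try:
            det.detect(img)
        except (RuntimeError, ValueError):
            return empty
        if det.positions is None or len(det.positions) == 0:
            return empty
        pts = det.positions[:, ::-1].astype(np.float64)
        scores = _shi_tomasi_at(corner_shi_tomasi(img), pts)

    h, w = img.shape
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
    )
    pts, scores = pts[inside], scores[inside]
    order = np.argsort(scores)[::-1]
    pts, scores = pts[order], scores[order]
    return KeypointSet(
        points=pts[:max_keypoints], responses=scores[:max_keypoints], method=method
    )


def track_keypoints(
    prev: np.ndarray,
    curr: np.ndarray,
    kps: KeypointSet,
    flow_params: FlowParams = FlowParams(),
    fb_threshold_px: float = 1.0,
) -> MatchedPairs:
    """Track keypoints from ``prev`` into ``curr`` with validation.

    Points failing the tracker status in either direction, or whose
    forward–backward round trip exceeds ``fb_threshold_px``, are dropped.
    """
    if prev.shape != curr.shape:
        raise ValueError("frames must share dimensions")
    if len(kps) == 0:
        return MatchedPairs(np.empty((0, 2)), np.empty((0, 2)))
    fwd, st_f = track_points(prev, curr, kps.points, flow_params)
    back, st_b = track_points(curr, prev, fwd, flow_params)
    fb_err = np.hypot(*(back - kps.points).T)
    keep = st_f & st_b & (fb_err <= fb_threshold_px)
    return MatchedPairs(prev_pts=kps.points[keep], curr_pts=fwd[keep])


# ---------------------------------------------------------------------------
# similarity estimation (RANSAC + closed-form least squares)
# ---------------------------------------------------------------------------


def _fit_similarity_lsq(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform | None:
    """Least-squares 4-DOF similarity src -> dst via the complex form.

    Writing points as complex numbers, the model is ``z' = a z + b`` with
    ``a = s e^{i theta}``; the LS solution is a = cov(z, z')/var(z).
    """
    z = src[:, 0] + 1j * src[:, 1]
    zp = dst[:, 0] + 1j * dst[:, 1]
    mz, mzp = z.mean(), zp.mean()
    denom = np.sum(np.abs(z - mz) ** 2)
    if denom < 1e-12:
        return None
    a = np.sum(np.conj(z - mz) * (zp - mzp)) / denom
    s = abs(a)
    if s <= 0:
        return None
    b = mzp - a * mz
    return SimilarityTransform(s=s, theta=float(np.angle(a)), dx=b.real, dy=b.imag)


def _residuals(t: SimilarityTransform, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    pred = t.apply(src)
    return np.hypot(pred[:, 0] - dst[:, 0], pred[:, 1] - dst[:, 1])


@dataclass
class EstimationResult:
    transform: SimilarityTransform
    failed: bool
    n_inliers: int = 0


def estimate_transform(
    pairs: MatchedPairs,
    min_pairs: int = 3,
    ransac_threshold_px: float = 3.0,
    confidence: float = 0.99,
    max_iter: int = 2000,
    seed: int = 0,
) -> EstimationResult:
    """Robustly fit the similarity mapping prev coordinates to curr.

    RANSAC with 2-point minimal samples and an inlier gate of
    ``ransac_threshold_px``, refined by least squares on the inlier set.
    Fewer than ``min_pairs`` correspondences yields the identity sentinel
    with ``failed=True`` (the chain keeps its length; the frame is flagged).
    """
    n = pairs.valid_count
    if n < min_pairs:
        return EstimationResult(identity(), failed=True)
    src, dst = pairs.prev_pts, pairs.curr_pts
    rng = np.random.default_rng(seed)

    best_inliers: np.ndarray | None = None
    best_count = 0
    n_iter = max_iter
    it = 0
    while it < n_iter:
        it += 1
        i, j = rng.choice(n, size=2, replace=False)
        z1, z2 = src[i, 0] + 1j * src[i, 1], src[j, 0] + 1j * src[j, 1]
        if abs(z2 - z1) < 1e-9:
            continue
        w1, w2 = dst[i, 0] + 1j * dst[i, 1], dst[j, 0] + 1j * dst[j, 1]
        a = (w2 - w1) / (z2 - z1)
        if abs(a) <= 0:
            continue
        b = w1 - a * z1
        cand = SimilarityTransform(
            s=abs(a), theta=float(np.angle(a)), dx=b.real, dy=b.imag
        )
        inliers = _residuals(cand, src, dst) < ransac_threshold_px
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
            # adaptive iteration bound from the current inlier ratio
            ratio = count / n
            if ratio > 0:
                p_good = ratio**2
                if p_good >= 1.0 - 1e-12:
                    break
                needed = int(np.ceil(np.log(1 - confidence) / np.log(1 - p_good)))
                n_iter = min(max_iter, max(needed, 1))

    if best_inliers is None or best_count < min_pairs:
        return EstimationResult(identity(), failed=True)
    refined = _fit_similarity_lsq(src[best_inliers], dst[best_inliers])
    if refined is None:
        return EstimationResult(identity(), failed=True)
    # tightened refinement: coherently moving transients (RBCs drifting a
    # pixel or two per frame) survive the consensus gate and bias the fit;
    # two refit rounds on a threshold/3 residual gate suppress them while
    # keeping genuinely static structure
    n_inliers = best_count
    for _ in range(2):
        close = _residuals(refined, src, dst) < ransac_threshold_px / 3.0
        if close.sum() < max(min_pairs, 10):
            break
        tighter = _fit_similarity_lsq(src[close], dst[close])
        if tighter is None:
            break
        refined, n_inliers = tighter, int(close.sum())
    return EstimationResult(refined, failed=False, n_inliers=n_inliers)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def estimate_motion_path(
    frames: list[np.ndarray],
    method: str = "gftt",
    params: StabilizerParams = StabilizerParams(),
) -> tuple[MotionPath, list[bool]]:
    """Estimate inter-frame transforms for a sequence (no warping).

    Returns the motion path (inter transforms ``T_i`` mapping frame i-1
    coordinates to frame i, plus the cumulative inverse chain) and a
    per-link failure flag.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    h, w = frames[0].shape
    for f in frames:
        if f.shape != (h, w):
            raise ValueError("frames must share dimensions")
    inter: list[SimilarityTransform] = []
    flags: list[bool] = []
    for i in range(len(frames) - 1):
        kps = detect_keypoints(frames[i], method, params.max_keypoints)
        pairs = track_keypoints(
            frames[i], frames[i + 1], kps, params.flow, params.fb_threshold_px
        )
        est = estimate_transform(
            pairs,
            min_pairs=params.min_pairs,
            ransac_threshold_px=params.ransac_threshold_px,
            confidence=params.ransac_confidence,
            max_iter=params.ransac_max_iter,
            seed=params.seed + i,
        )
        logger.info(
            "pair %d->%d: %d keypoints, %d tracked, %d inliers%s",
            i, i + 1, len(kps), pairs.valid_count, est.n_inliers,
            " [estimation failed]" if est.failed else "",
        )
        inter.append(est.transform)
        flags.append(est.failed)
    return MotionPath.from_inter(inter), flags


def stabilize(
    frames: list[np.ndarray],
    method: str = "gftt",
    params: StabilizerParams = StabilizerParams(),
) -> tuple[list[np.ndarray], MotionPath, list[bool]]:
    """Stabilize a sequence against its first frame.

    Each frame ``i >= 1`` is warped by the cumulative inverse chain
    ``C_i = T_1^-1 . T_2^-1 ... T_{i-1}^-1 ... `` so that all frames align
    with frame 0; frame 0 is returned unchanged.
    """
    path, flags = estimate_motion_path(frames, method, params)
    out = [frames[0]]
    for i in range(1, len(frames)):
        c = path.cumulative[i]
        if c.is_close(identity(), tol=0.0):
            out.append(frames[i].copy())
        else:
            out.append(warp_frame(frames[i], to_matrix(c)))
    return out, path, flags
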