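"""Stabilization quality metrics.

Four complementary views of a stabilized video:

* **SSIM** — windowed structural similarity between each stabilized frame
  and its stable reference frame (luminance/contrast/structure product over
  11x11 Gaussian-weighted windows, constants c1=(0.01*255)^2,
  c2=(0.03*255)^2); in [-1, 1], 1 = structurally identical.
* **Jitter Index** — the standard deviation of inter-frame displacement
  magnitudes (pixels); lower = temporally steadier.
* **Path Smoothness Index** — mean norm of the second difference of the
  cumulative translation path, normalised by the image diagonal
  (dimensionless); zero for static or constant-velocity paths.
* **Geometric RMS errors** — RMS difference between recovered and
  ground-truth motion parameters (dx, dy in pixels, rotation in degrees).

For jitter and smoothness of an evaluated sequence, the residual motion is
re-estimated between consecutive output frames, so the metrics apply to
any video, with or without ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .geometry import (
    MotionPath,
    SimilarityTransform,
    invert,
    params_about_center,
    to_matrix,
)

__all__ = [
    "ssim",
    "video_ssim",
    "jitter_index",
    "path_smoothness",
    "rms_errors",
    "evaluate",
    "StabilizationReport",
    "REPORT_CSV_HEADER",
    "write_report_csv",
]

REPORT_CSV_HEADER = (
    "mean_ssim,ssim_std,jitter_index,path_smoothness,"
    "rms_dx,rms_dy,rms_rotation_deg,exec_time_s,method,sigma,seed"
)

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5   # 11x11 kernel at sigma 1.5
_SSIM_PAD = 5


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    c1: float = (0.01 * 255) ** 2,
    c2: float = (0.03 * 255) ** 2,
) -> float:
    """Mean structural similarity of two 8-bit-range grayscale frames.

    Local means, variances and covariance are computed over an 11x11
    Gaussian-weighted window (sigma 1.5); the local map

        SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
               / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    is mean-pooled over the frame interior (a 5-pixel border, where the
    window hangs off the frame, is excluded).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("frames must share dimensions")
    if min(x.shape) < 11:
        raise ValueError("frames smaller than the 11x11 SSIM window")

    def g(a: np.ndarray) -> np.ndarray:
        return ndi.gaussian_filter(a, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ux, uy = g(x), g(y)
    vx = g(x * x) - ux * ux
    vy = g(y * y) - uy * uy
    cxy = g(x * y) - ux * uy
    smap = ((2 * ux * uy + c1) * (2 * cxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    p = _SSIM_PAD
    return float(smap[p:-p, p:-p].mean())


def video_ssim(
    reference: Sequence[np.ndarray], test: Sequence[np.ndarray]
) -> tuple[float, float]:
    """Mean and std of per-frame SSIM against the reference sequence.

    Frame 0 is excluded: it is the untouched reference frame in both the
    perturbed and the stabilized sequence and would inflate the mean.
    """
    if len(reference) != len(test):
        raise ValueError("sequences must have equal length")
    if len(reference) < 2:
        raise ValueError("need at least two frames to compare")
    scores = [ssim(r, t) for r, t in zip(reference[1:], test[1:])]
    return float(np.mean(scores)), float(np.std(scores))


def jitter_index(path: MotionPath) -> float:
    """Population std of inter-frame displacement magnitudes, in pixels."""
    d = path.inter_displacements()
    if len(d) < 2:
        raise ValueError("need at least two inter-frame transforms")
    return float(np.std(d))


def path_smoothness(path: MotionPath, width: int, height: int) -> float:
    """Mean second-difference norm of the cumulative translation path.

    Normalised by the image diagonal; 0 for static or uniform-velocity
    trajectories, larger for erratic ones.
    """
    pos = path.cumulative_translations()
    if len(pos) < 3:
        raise ValueError("need at least three cumulative positions")
    acc = np.diff(pos, n=2, axis=0)
    diag = math.hypot(width, height)
    return float(np.mean(np.hypot(acc[:, 0], acc[:, 1])) / diag)


def rms_errors(
    estimated: Sequence[SimilarityTransform],
    truth: Sequence[SimilarityTransform],
    width: int,
    height: int,
) -> tuple[float, float, float]:
    """RMS parameter-recovery errors: (dx px, dy px, rotation degrees).

    Both lists must describe per-frame motion in the same direction and
    about the same pivot (use :func:`capstab.geometry.params_about_center`
    to centre-normalise matrices estimated about the origin).
    """
    if len(estimated) != len(truth):
        raise ValueError("lists must have equal length")
    if not estimated:
        raise ValueError("empty transform lists")
    ddx = np.array([e.dx - t.dx for e, t in zip(estimated, truth)])
    ddy = np.array([e.dy - t.dy for e, t in zip(estimated, truth)])
    dth = np.array(
        [
            math.atan2(math.sin(e.theta - t.theta), math.cos(e.theta - t.theta))
            for e, t in zip(estimated, truth)
        ]
    )
    rms = lambda a: float(np.sqrt(np.mean(a**2)))
    return rms(ddx), rms(ddy), math.degrees(rms(dth))


@dataclass
class StabilizationReport:
    """Per-video metric bundle (one row of the benchmark table)."""

    mean_ssim: float
    ssim_std: float
    jitter_index: float
    path_smoothness: float
    rms_dx: float
    rms_dy: float
    rms_rotation_deg: float
    exec_time_s: float
    method: str
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.mean_ssim <= 1.0):
            raise ValueError("mean SSIM outside [-1, 1]")
        for name in ("jitter_index", "path_smoothness", "rms_dx", "rms_dy",
                     "rms_rotation_deg"):
            v = getattr(self, name)
            if not (math.isnan(v) or v >= 0):
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def recovered_perturbations(
    estimated_path: MotionPath, width: int, height: int
) -> list[SimilarityTransform]:
    """Per-frame perturbation estimates implied by a cumulative chain.

    The cumulative transform ``C_i`` aligns frame i back to the reference,
    so ``C_i^-1`` is the pipeline's estimate of the perturbation applied to
    frame i; it is centre-normalised for comparison with the simulator's
    centre-pivot ground truth.
    """
    out = []
    for c in estimated_path.cumulative[1:]:
        out.append(params_about_center(to_matrix(invert(c)), width, height))
    return out


def evaluate(
    reference: Sequence[np.ndarray],
    stabilized: Sequence[np.ndarray],
    truth: Sequence[SimilarityTransform] | None = None,
    estimated_path: MotionPath | None = None,
    exec_time_s: float = float("nan"),
    method: str = "",
    sigma: float = float("nan"),
    seed: int = 0,
    residual_method: str = "gftt",
) -> StabilizationReport:
    """Assemble the full per-video report.

    SSIM is computed frame-by-frame between ``reference`` and
    ``stabilized``.  Jitter and path smoothness are computed from residual
    motion re-estimated between consecutive frames of ``stabilized``
    (detector ``residual_method``).  If ``truth`` and ``estimated_path``
    are given, geometric RMS recovery errors are included, else NaN.
    """
    from .stabilization import estimate_motion_path  # local: avoid cycle

    mean_s, std_s = video_ssim(reference, stabilized)
    h, w = np.asarray(reference[0]).shape
    residual, _ = estimate_motion_path(list(stabilized), method=residual_method)
    jit = jitter_index(residual)
    smooth = path_smoothness(residual, w, h)
    if truth is not None and estimated_path is not None:
        recovered = recovered_perturbations(estimated_path, w, h)
        rdx, rdy, rrot = rms_errors(recovered, truth, w, h)
    else:
        rdx = rdy = rrot = float("nan")
    return StabilizationReport(
        mean_ssim=mean_s,
        ssim_std=std_s,
        jitter_index=jit,
        path_smoothness=smooth,
        rms_dx=rdx,
        rms_dy=rdy,
        rms_rotation_deg=rrot,
        exec_time_s=exec_time_s,
        method=method,
        sigma=sigma,
        seed=seed,
    )


def write_report_csv(path: str | Path, reports: Sequence[StabilizationReport]) -> None:
    cols = REPORT_CSV_HEADER.split(",")
    lines = [REPORT_CSV_HEADER]
    for r in reports:
        d = r.to_dict()
        lines.append(",".join(repr(d[c]) if isinstance(d[c], float) else str(d[c])
                              for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
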