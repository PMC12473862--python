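"""Synthetic capillaroscopy scenes and ground-truth tremor simulation.

Clinical oral-capillaroscopy footage shows dark curvilinear capillaries on
a bright, noisy mucosal background, with red blood cells (RBCs) drifting
along the vessels.  No public dataset accompanies the method, so this
module renders a synthetic stand-in with those gross features and then
perturbs it with the documented tremor model: each frame is independently
warped by a random similarity transform whose parameters are drawn from
zero-mean Gaussians —

* translation: ``dx ~ width * N(0, sigma_t^2)``, ``dy ~ height * N(0, sigma_t^2)``
  (translations are normalised by the image dimensions),
* rotation: ``theta ~ N(0, sigma_r^2)`` radians,
* scale: ``s ~ N(1, sigma_s^2)``.

Perturbations pivot about the image centre (a tremor that rotated about
the corner would mostly translate the field of view).  Frame 0 is left
untouched as the stabilization reference, and every ground-truth transform
is logged so recovery error can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import interpolate, ndimage as ndi

from .geometry import SimilarityTransform, about_center, identity
from .warping import warp_frame

__all__ = [
    "TremorConfig",
    "SceneSpec",
    "ILLUMINATION_AMPLITUDE",
    "sample_perturbation",
    "perturb_sequence",
    "render_frame",
    "render_sequence",
]

# Peak deviation of the low-frequency illumination field, in grey levels.
ILLUMINATION_AMPLITUDE = 12.0


@dataclass(frozen=True)
class TremorConfig:
    """Tremor intensity: Gaussian sigmas for the three motion channels.

    The benchmark sweeps one sigma value applied simultaneously to all
    three channels over [0.005, 0.01], mimicking comparable relative
    perturbations across motion types.
    """

    sigma_t: float = 0.01  # std of translation as a fraction of width/height
    sigma_r: float = 0.01  # std of rotation, radians
    sigma_s: float = 0.01  # std of scale about 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_t, self.sigma_r, self.sigma_s) < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic capillary scene.

    Defaults emulate the acquisition format of the target instrument:
    640x480, 8-bit grayscale, bright background (~200/255) with mild
    sensor noise, a dozen dark capillary-like curves of a few pixels
    half-width, and slowly drifting RBC blobs along them.
    """

    width: int = 640
    height: int = 480
    n_vessels: int = 12
    vessel_width_px: float = 2.5
    background_level: float = 200.0
    noise_sigma: float = 4.0
    n_rbc: int = 15
    rbc_speed_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("zero-area image")


def sample_perturbation(
    config: TremorConfig,
    rng: np.random.Generator,
    width: int,
    height: int,
) -> SimilarityTransform:
    """Draw one tremor transform; rng is consumed in order (dx, dy, theta, s).

    A scale draw at or below 0.5 (a vanishing-field degenerate warp,
    negligible probability at realistic sigmas) is rejected and redrawn.
    """
    dx = width * rng.normal(0.0, config.sigma_t)
    dy = height * rng.normal(0.0, config.sigma_t)
    theta = rng.normal(0.0, config.sigma_r)
    s = rng.normal(1.0, config.sigma_s)
    while s <= 0.5:
        s = rng.normal(1.0, config.sigma_s)
    return SimilarityTransform(s=s, theta=theta, dx=dx, dy=dy)


def perturb_sequence(
    frames: list[np.ndarray], config: TremorConfig
) -> tuple[list[np.ndarray], list[SimilarityTransform]]:
    """Warp each frame i >= 1 by an independent tremor transform.

    Frame 0 is the unperturbed reference.  Transforms pivot at the image
    centre (bilinear interpolation, reflection padding).  Returns the
    perturbed frames and the ground-truth transforms ``T_1 .. T_{n-1}``.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    h, w = frames[0].shape
    for f in frames:
        if f.shape != (h, w):
            raise ValueError("frames must share dimensions")
    rng = np.random.default_rng(config.seed)
    out = [frames[0]]
    truth: list[SimilarityTransform] = []
    for f in frames[1:]:
        t = sample_perturbation(config, rng, w, h)
        truth.append(t)
        if t.is_close(identity(), tol=0.0):
            out.append(f.copy())
        else:
            out.append(warp_frame(f, about_center(t, w, h)))
    return out, truth


def _spline_curve(
    rng: np.random.Generator, width: int, height: int, n_samples: int = 1200
) -> np.ndarray:
    """One smooth capillary-like curve: (n_samples, 2) float (x, y) points."""
    k = 6
    # a loose directed walk across the image keeps curves smooth but wandering
    x = np.sort(rng.uniform(0.05, 0.95, size=k)) * width
    y = rng.uniform(0.08, 0.92, size=k) * height
    if rng.random() < 0.5:
        x, y = y / height * width, x / width * height  # vary dominant direction
    try:
        (tck, _) = interpolate.splprep([x, y], s=0.0, k=3)
        u = np.linspace(0.0, 1.0, n_samples)
        xs, ys = interpolate.splev(u, tck)
    except Exception:  # nearly-coincident control points: fall back to polyline
        u = np.linspace(0.0, 1.0, n_samples)
        xs = np.interp(u, np.linspace(0, 1, k), x)
        ys = np.interp(u, np.linspace(0, 1, k), y)
    pts = np.stack([xs, ys], axis=1)
    pts[:, 0] = np.clip(pts[:, 0], 0, width - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, height - 1)
    return pts


@lru_cache(maxsize=8)
def _static_scene(spec: SceneSpec):
    """Static layers of the scene: background+vessel image, curves, RBC lots.

    Deterministic in ``spec`` alone; cached because every frame of a
    sequence shares it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # low-frequency illumination: a single oblique sinusoid, bounded by
    # ILLUMINATION_AMPLITUDE so a structure-free scene stays in a known band
    fx, fy = rng.uniform(0.4, 1.2, size=2)
    phase = rng.uniform(0, 2 * np.pi)
    illum = ILLUMINATION_AMPLITUDE * np.cos(
        2 * np.pi * (fx * xx / w + fy * yy / h) + phase
    )
    base = spec.background_level + illum

    curves: list[np.ndarray] = []
    for _ in range(spec.n_vessels):
        curves.append(_spline_curve(rng, w, h))
        depth = rng.uniform(60.0, 100.0)
        mask = np.ones((h, w), dtype=bool)
        ix = np.clip(np.rint(curves[-1][:, 0]).astype(int), 0, w - 1)
        iy = np.clip(np.rint(curves[-1][:, 1]).astype(int), 0, h - 1)
        mask[iy, ix] = False
        d = ndi.distance_transform_edt(mask)
        base -= depth * np.exp(-(d**2) / (2.0 * spec.vessel_width_px**2))

    # static RBC lot assignments: (vessel index, arc offset in samples)
    rbc: list[tuple[int, float]] = []
    if curves:
        for _ in range(spec.n_rbc):
            rbc.append((int(rng.integers(len(curves))), float(rng.uniform(0, 1) )))
    return base, curves, rbc


def _rbc_layer(spec: SceneSpec, phase: int, curves, rbc) -> np.ndarray:
    """Dark circular blobs positioned along vessels at the given phase."""
    h, w = spec.height, spec.width
    layer = np.zeros((h, w), dtype=np.float64)
    if not rbc:
        return layer
    blob_sigma, blob_depth, rad = 2.5, 45.0, 8
    for vessel_idx, offset01 in rbc:
        pts = curves[vessel_idx]
        seg = np.hypot(*np.diff(pts, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        pos = (offset01 * arc[-1] + phase * spec.rbc_speed_px) % arc[-1]
        i = int(np.searchsorted(arc, pos))
        cx, cy = pts[min(i, len(pts) - 1)]
        x0, x1 = int(cx) - rad, int(cx) + rad + 1
        y0, y1 = int(cy) - rad, int(cy) + rad + 1
        xs = np.arange(max(x0, 0), min(x1, w))
        ys = np.arange(max(y0, 0), min(y1, h))
        if xs.size == 0 or ys.size == 0:
            continue
        gx, gy = np.meshgrid(xs, ys)
        layer[gy, gx] -= blob_depth * np.exp(
            -((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * blob_sigma**2)
        )
    return layer


def render_frame(spec: SceneSpec, phase: int = 0) -> np.ndarray:
    """Render one 8-bit frame; deterministic in (spec, phase)."""
    base, curves, rbc = _static_scene(spec)
    img = base + _rbc_layer(spec, phase, curves, rbc)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101, phase]))
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_sequence(spec: SceneSpec, n_frames: int) -> list[np.ndarray]:
    """Frames at phase 0..n_frames-1: static vessels, drifting RBCs, fresh noise."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return [render_frame(spec, p) for p in range(n_frames)]
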