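"""Sparse pyramidal Lucas–Kanade optical flow.

Per-keypoint displacement between two frames under the brightness-constancy
constraint ``Ix*u + Iy*v + It = 0``, solved over a local window by iterative
Gauss–Newton refinement on a coarse-to-fine image pyramid.  Defaults follow
the common configuration for this tracker: 21x21 window, 3 pyramid levels,
and termination after 30 iterations or when the update norm drops below
0.01 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["FlowParams", "track_points"]


@dataclass(frozen=True)
class FlowParams:
    window: int = 21        # side of the square correlation window, pixels
    levels: int = 3         # pyramid levels (full resolution included)
    max_iter: int = 30
    eps: float = 0.01       # convergence threshold on the update norm, px
    min_eig: float = 1e-4   # reject points whose normalised gradient matrix
                            # has a smaller minimum eigenvalue (flat window)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, downscale 2 per level, level 0 = full resolution."""
    levs = [img.astype(np.float64)]
    for _ in range(levels - 1):
        smoothed = ndi.gaussian_filter(levs[-1], sigma=1.0, mode="mirror")
        levs.append(smoothed[::2, ::2])
    return levs


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(img, [ys, xs], order=1, mode="mirror")


def track_points(
    prev: np.ndarray,
    curr: np.ndarray,
    points: np.ndarray,
    params: FlowParams = FlowParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Track (x, y) points from ``prev`` into ``curr``.

    Returns ``(new_points, status)`` where status is False for points whose
    local gradient matrix is degenerate or whose track leaves the frame.
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError("frames must share dimensions")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)

    h, w = prev.shape
    pyr_prev = _pyramid(prev, params.levels)
    pyr_curr = _pyramid(curr, params.levels)

    r = params.window // 2
    off = np.arange(-r, r + 1, dtype=np.float64)
    ox, oy = np.meshgrid(off, off)           # (win, win) window offsets
    ox, oy = ox.ravel(), oy.ravel()          # (win*win,)
    win_area = float(params.window**2)

    status = np.ones(n, dtype=bool)
    flow = np.zeros((n, 2), dtype=np.float64)  # displacement at current level

    for level in range(params.levels - 1, -1, -1):
        scale = 2.0**level
        ip, ic = pyr_prev[level], pyr_curr[level]
        gy, gx = np.gradient(ip)
        p_lvl = pts / scale                   # template positions at this level

        # per-point window coordinates on the template frame
        wx = p_lvl[:, 0:1] + ox[None, :]      # (n, win*win)
        wy = p_lvl[:, 1:2] + oy[None, :]
        patch0 = _sample(ip, wx, wy)
        Ix = _sample(gx, wx, wy)
        Iy = _sample(gy, wx, wy)
        gxx = np.sum(Ix * Ix, axis=1)
        gxy = np.sum(Ix * Iy, axis=1)
        gyy = np.sum(Iy * Iy, axis=1)
        det = gxx * gyy - gxy * gxy
        tr = gxx + gyy
        min_eig = (tr - np.sqrt(np.maximum(tr * tr - 4 * det, 0.0))) / 2.0
        ok = (min_eig / win_area) >= params.min_eig
        status &= ok

        v = flow.copy()
        active = status.copy()
        for _ in range(params.max_iter):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            cx = wx[idx] + v[idx, 0:1]
            cy = wy[idx] + v[idx, 1:2]
            diff = patch0[idx] - _sample(ic, cx, cy)
            bx = np.sum(diff * Ix[idx], axis=1)
            by = np.sum(diff * Iy[idx], axis=1)
            d = det[idx]
            ux = (gyy[idx] * bx - gxy[idx] * by) / d
            uy = (gxx[idx] * by - gxy[idx] * bx) / d
            v[idx, 0] += ux
            v[idx, 1] += uy
            active[idx] = np.hypot(ux, uy) >= params.eps
        flow = v
        if level > 0:
            flow = flow * 2.0                 # propagate to the finer level

    new_pts = pts + flow
    inside = (
        (new_pts[:, 0] >= 0)
        & (new_pts[:, 0] <= w - 1)
        & (new_pts[:, 1] >= 0)
        & (new_pts[:, 1] <= h - 1)
    )
    status &= inside & np.all(np.isfinite(new_pts), axis=1)
    return new_pts, status
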