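"""Frame resampling under a similarity/affine matrix.

Warping uses inverse mapping with bilinear interpolation; samples falling
outside the frame are filled by reflection padding about the border
(mirror convention, edge pixel not repeated), which preserves edge
continuity and avoids artificial gradients at the warped borders.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["warp_frame"]


def _homogeneous(M: np.ndarray) -> np.ndarray:
    H = np.eye(3)
    H[:2, :] = M
    return H


def warp_frame(frame: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a forward 2x3 matrix to a grayscale frame.

    ``matrix`` maps input (x, y) coordinates to output coordinates; each
    output pixel is resampled from the input at the inverse-mapped
    location.  Output has the same shape and dtype as the input (8-bit
    frames are rounded and clipped back to uint8).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    M = np.asarray(matrix, dtype=np.float64)
    if M.shape == (3, 3):
        M = M[:2, :]
    if M.shape != (2, 3):
        raise ValueError(f"expected a 2x3 matrix, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix entries must be finite")

    Hinv = np.linalg.inv(_homogeneous(M))
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    xs = Hinv[0, 0] * xx + Hinv[0, 1] * yy + Hinv[0, 2]
    ys = Hinv[1, 0] * xx + Hinv[1, 1] * yy + Hinv[1, 2]
    out = ndi.map_coordinates(
        frame.astype(np.float64), [ys, xs], order=1, mode="mirror"
    )
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(frame.dtype)
    return out.astype(frame.dtype)
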