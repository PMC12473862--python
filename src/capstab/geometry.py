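"""Algebra of the 4-DOF similarity motion model.

The inter-frame motion of a capillaroscopy probe is modelled as a planar
similarity: uniform scale ``s``, rotation ``theta`` and translation
``(dx, dy)``.  Its action on a point written as a column vector
``[x, y, 1]^T`` (x = column index, y = row index, origin at the top-left
pixel centre) is the 2x3 matrix

    [[ s*cos(theta), -s*sin(theta), dx ],
     [ s*sin(theta),  s*cos(theta), dy ]]

All composition follows matrix convention: ``compose(a, b)`` applies ``b``
first, then ``a``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimilarityTransform",
    "MotionPath",
    "NotSimilarityError",
    "identity",
    "to_matrix",
    "from_matrix",
    "invert",
    "compose",
    "about_center",
    "params_about_center",
    "write_transforms_csv",
    "read_transforms_csv",
]

TRANSFORM_CSV_HEADER = ["frame_index", "s", "theta_rad", "dx_px", "dy_px"]


class NotSimilarityError(ValueError):
    """Raised when a 2x3 matrix is not a positive-scale rotation-scaling."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity motion parameters.

    Parameters
    ----------
    s : float
        Scale factor, strictly positive.
    theta : float
        Rotation angle in radians, stored in (-pi, pi].
    dx, dy : float
        Translation in pixels along x (columns) and y (rows).
    """

    s: float = 1.0
    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise ValueError(f"scale must be > 0, got {self.s}")
        # canonical angle in (-pi, pi]
        t = math.atan2(math.sin(self.theta), math.cos(self.theta))
        object.__setattr__(self, "theta", t)
        for name in ("s", "theta", "dx", "dy"):
            object.__setattr__(self, name, float(getattr(self, name)))

    # Convenience aliases so the algebra reads naturally from the instance.
    def matrix(self) -> np.ndarray:
        return to_matrix(self)

    def inverse(self) -> "SimilarityTransform":
        return invert(self)

    def __matmul__(self, other: "SimilarityTransform") -> "SimilarityTransform":
        return compose(self, other)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points through the transform."""
        pts = np.asarray(points, dtype=np.float64)
        m = to_matrix(self)
        return pts @ m[:, :2].T + m[:, 2]

    def is_close(self, other: "SimilarityTransform", tol: float = 1e-9) -> bool:
        dtheta = math.atan2(
            math.sin(self.theta - other.theta), math.cos(self.theta - other.theta)
        )
        return (
            abs(self.s - other.s) <= tol
            and abs(dtheta) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


def identity() -> SimilarityTransform:
    return SimilarityTransform(1.0, 0.0, 0.0, 0.0)


def to_matrix(t: SimilarityTransform) -> np.ndarray:
    """2x3 matrix realisation acting on column vectors [x, y, 1]^T."""
    c = t.s * math.cos(t.theta)
    s = t.s * math.sin(t.theta)
    return np.array([[c, -s, t.dx], [s, c, t.dy]], dtype=np.float64)


def from_matrix(M: np.ndarray, rtol: float = 1e-6) -> SimilarityTransform:
    """Recover (s, theta, dx, dy) from a 2x3 similarity matrix.

    The 2x2 linear part must be a positive-scale rotation-scaling: columns
    orthogonal, of equal norm, with positive determinant.  Shear or
    reflection beyond ``rtol`` (relative) raises :class:`NotSimilarityError`.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape == (3, 3):
        M = M[:2, :]
    if M.shape != (2, 3):
        raise ValueError(f"expected a 2x3 matrix, got shape {M.shape}")
    A = M[:, :2]
    c0, c1 = A[:, 0], A[:, 1]
    n0, n1 = np.linalg.norm(c0), np.linalg.norm(c1)
    scale = max(n0, n1)
    if scale == 0:
        raise NotSimilarityError("zero linear part")
    if abs(n0 - n1) > rtol * scale or abs(float(c0 @ c1)) > rtol * scale**2:
        raise NotSimilarityError("linear part has shear or anisotropic scale")
    if np.linalg.det(A) <= 0:
        raise NotSimilarityError("linear part contains a reflection")
    s = math.sqrt(M[0, 0] ** 2 + M[1, 0] ** 2)
    theta = math.atan2(M[1, 0], M[0, 0])
    return SimilarityTransform(s, theta, M[0, 2], M[1, 2])


def invert(t: SimilarityTransform) -> SimilarityTransform:
    """Inverse transform: s' = 1/s, theta' = -theta, translation conjugated."""
    c = math.cos(t.theta) / t.s
    s = math.sin(t.theta) / t.s
    # translation of the inverse is -R(-theta)/s applied to (dx, dy)
    dx = -(c * t.dx + s * t.dy)
    dy = -(-s * t.dx + c * t.dy)
    return SimilarityTransform(1.0 / t.s, -t.theta, dx, dy)


def compose(a: SimilarityTransform, b: SimilarityTransform) -> SimilarityTransform:
    """Transform whose matrix is matrix(a) @ matrix(b): apply ``b`` first."""
    s = a.s * b.s
    theta = a.theta + b.theta
    ca, sa = math.cos(a.theta), math.sin(a.theta)
    dx = a.s * (ca * b.dx - sa * b.dy) + a.dx
    dy = a.s * (sa * b.dx + ca * b.dy) + a.dy
    return SimilarityTransform(s, theta, dx, dy)


def _center(width: int, height: int) -> tuple[float, float]:
    return (width - 1) / 2.0, (height - 1) / 2.0


def about_center(t: SimilarityTransform, width: int, height: int) -> np.ndarray:
    """Matrix of ``t`` conjugated so rotation/scale pivot at the image centre.

    Equals ``translate(+c) . t . translate(-c)`` with
    ``c = ((width-1)/2, (height-1)/2)``; the centre pixel maps to
    centre + (dx, dy).
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    cx, cy = _center(width, height)
    pre = SimilarityTransform(1.0, 0.0, -cx, -cy)
    post = SimilarityTransform(1.0, 0.0, cx, cy)
    return to_matrix(compose(post, compose(t, pre)))


def params_about_center(M: np.ndarray, width: int, height: int) -> SimilarityTransform:
    """Centre-pivot parameters of an origin-pivot 2x3 similarity matrix.

    Inverse of :func:`about_center` on the matrix level: returns ``t`` such
    that ``about_center(t, width, height)`` equals ``M``.
    """
    cx, cy = _center(width, height)
    pre = SimilarityTransform(1.0, 0.0, cx, cy)
    post = SimilarityTransform(1.0, 0.0, -cx, -cy)
    m = from_matrix(M)
    return compose(post, compose(m, pre))


@dataclass
class MotionPath:
    """Per-frame inter transforms plus their cumulative composition.

    ``inter[i]`` maps frame ``i`` coordinates to frame ``i+1`` coordinates;
    ``cumulative[i]`` maps frame ``i`` coordinates back to frame 0, built by
    chaining inverses: ``cumulative[i+1] = cumulative[i] . inter[i]^-1``,
    i.e. the left-to-right matrix product ``T1^-1 . T2^-1 ... Ti^-1``.
    """

    inter: list[SimilarityTransform]
    cumulative: list[SimilarityTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cumulative:
            self.cumulative = self._chain(self.inter)
        if len(self.cumulative) != len(self.inter) + 1:
            raise ValueError("len(cumulative) must equal len(inter) + 1")

    @staticmethod
    def _chain(inter: Sequence[SimilarityTransform]) -> list[SimilarityTransform]:
        cum = [identity()]
        for t in inter:
            cum.append(compose(cum[-1], invert(t)))
        return cum

    @classmethod
    def from_inter(cls, inter: Iterable[SimilarityTransform]) -> "MotionPath":
        return cls(inter=list(inter))

    def __len__(self) -> int:
        return len(self.cumulative)

    def cumulative_translations(self) -> np.ndarray:
        """(n_frames, 2) array of cumulative (dx, dy)."""
        return np.array([[t.dx, t.dy] for t in self.cumulative], dtype=np.float64)

    def inter_displacements(self) -> np.ndarray:
        """(n_links,) array of inter-frame displacement magnitudes."""
        d = np.array([[t.dx, t.dy] for t in self.inter], dtype=np.float64)
        if d.size == 0:
            return np.empty(0)
        return np.hypot(d[:, 0], d[:, 1])


def write_transforms_csv(
    path: str | Path, transforms: Sequence[SimilarityTransform], start_index: int = 1
) -> None:
    """Serialize a transform log: header frame_index,s,theta_rad,dx_px,dy_px."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRANSFORM_CSV_HEADER)
        for i, t in enumerate(transforms):
            w.writerow(
                [start_index + i, repr(t.s), repr(t.theta), repr(t.dx), repr(t.dy)]
            )


def read_transforms_csv(path: str | Path) -> list[SimilarityTransform]:
    path = Path(path)
    out: list[SimilarityTransform] = []
    with path.open(newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != TRANSFORM_CSV_HEADER:
            raise ValueError(f"unexpected transform CSV header: {header}")
        for row in r:
            _, s, theta, dx, dy = row
            out.append(SimilarityTransform(float(s), float(theta), float(dx), float(dy)))
    return out
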