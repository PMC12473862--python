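"""Reading and writing frame sequences.

The canonical interchange format is a lexicographically ordered directory
of lossless PNG (or TIFF) images — codec determinism matters when reports
must be bit-reproducible.  Video containers are read opportunistically
when an imageio plugin for them is available.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["read_sequence", "write_sequence"]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

# ITU-R BT.601 luma weights for color inputs
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray_u8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.dtype == np.uint8:
        return np.ascontiguousarray(img)
    if img.dtype == np.uint16:
        return (img // 257).astype(np.uint8)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def read_sequence(path: str | Path) -> list[np.ndarray]:
    """Load a video file or an image-sequence directory as 8-bit grayscale.

    Directory inputs are ordered lexicographically; mixed frame dimensions
    or an empty directory raise ``ValueError``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise ValueError(f"no frames found in directory {path}")
        frames = [_to_gray_u8(iio.imread(f)) for f in files]
    elif path.is_file():
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:
            raise ValueError(f"cannot decode {path}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2 or (raw.ndim == 3 and raw.shape[-1] in (3, 4)):
            frames = [_to_gray_u8(raw)]
        else:
            frames = [_to_gray_u8(fr) for fr in raw]
    else:
        raise ValueError(f"no such file or directory: {path}")
    h, w = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != (h, w):
            raise ValueError(f"frame {i} has shape {f.shape}, expected {(h, w)}")
    return frames


def write_sequence(
    frames: Sequence[np.ndarray],
    path: str | Path,
    fmt: str = "png",
) -> dict:
    """Write frames as a numbered lossless image sequence.

    Returns (and saves as ``manifest.json``) a manifest of filenames,
    dimensions and SHA-256 checksums of the pixel data.
    """
    if len(frames) == 0:
        raise ValueError("no frames to write")
    if fmt not in ("png", "tiff"):
        raise ValueError(f"unsupported format {fmt!r}")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, frame in enumerate(frames):
        frame = np.asarray(frame)
        name = f"frame_{i:05d}.{ 'png' if fmt == 'png' else 'tif'}"
        iio.imwrite(outdir / name, frame)
        entries.append(
            {
                "name": name,
                "width": int(frame.shape[1]),
                "height": int(frame.shape[0]),
                "sha256": hashlib.sha256(frame.tobytes()).hexdigest(),
            }
        )
    manifest = {"count": len(entries), "format": fmt, "files": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
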