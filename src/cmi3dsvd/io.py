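"""Grayscale image I/O helpers (PNG/TIFF)."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_gray", "write_gray", "read_labels", "write_labels"]


def read_gray(path) -> np.ndarray:
    """Read an image as a float 2D array on the 0-255 scale."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A) by luminance-free channel average
        arr = arr[..., :3].mean(axis=2)
    arr = arr.astype(float)
    if arr.max() > 255.0:  # 16-bit input: rescale to the 0-255 convention
        arr = arr * (255.0 / arr.max())
    return arr


def write_gray(path, img: np.ndarray) -> None:
    """Write a float image as 8-bit grayscale (clipped and rounded)."""
    out = np.clip(np.asarray(img, dtype=float), 0, 255).round().astype(np.uint8)
    iio.imwrite(path, out)


def read_labels(path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


def write_labels(path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit PNG."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    iio.imwrite(path, lab.astype(np.uint16))
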