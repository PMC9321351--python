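"""Texture features and texture-augmented superpixel segmentation.

The local tri-directional pattern (LTriDP) encodes, for each of the eight
neighbors of a pixel, a comparison between two squared-difference magnitudes
into an 8-bit code.  The code is used as a scalar texture feature in a
grayscale SLIC variant whose clustering distance combines gray value,
spatial proximity and texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "NEIGHBOR_OFFSETS",
    "TextureMap",
    "LabelMap",
    "ltridp_window",
    "ltridp_map",
    "count_histogram_peaks",
    "slic_superpixels",
]

#: 3x3 neighbor offsets (row, col) in circular order, clockwise from the
#: top-left corner: p1=NW, p2=N, p3=NE, p4=E, p5=SE, p6=S, p7=SW, p8=W.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass(frozen=True)
class TextureMap:
    """Per-pixel LTriDP code (0..255) and the underlying 8 magnitude bits."""

    code: np.ndarray = field(repr=False)          # (H, W) uint8
    magnitude_bits: np.ndarray = field(repr=False)  # (H, W, 8) uint8


@dataclass(frozen=True)
class LabelMap:
    """Superpixel assignment: labels in [0, K-1] plus per-cluster centers."""

    labels: np.ndarray = field(repr=False)  # (H, W) int
    K: int
    centers: dict = field(repr=False)  # arrays: gray, row, col, tex (len K)


def ltridp_window(window: np.ndarray) -> np.ndarray:
    """Magnitude bits of the central pixel of a 3x3 window.

    For neighbor t (circular, 1..8) with center ``pc``::

        M1 = (p[t-1] - pc)^2 + (p[t+1] - pc)^2
        M2 = (p[t-1] - pc)^2 + (p[t+1] - p[t])^2
        bit_t = 1  if M1 >= M2 else 0
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (3, 3):
        raise ValueError(f"expected a 3x3 window, got shape {w.shape}")
    pc = w[1, 1]
    p = np.array([w[1 + dr, 1 + dc] for dr, dc in NEIGHBOR_OFFSETS])
    bits = np.empty(8, dtype=np.uint8)
    for t0 in range(8):
        p_prev = p[(t0 - 1) % 8]
        p_t = p[t0]
        p_next = p[(t0 + 1) % 8]
        m1 = (p_prev - pc) ** 2 + (p_next - pc) ** 2
        m2 = (p_prev - pc) ** 2 + (p_next - p_t) ** 2
        bits[t0] = 1 if m1 >= m2 else 0
    return bits


def ltridp_map(img: np.ndarray) -> TextureMap:
    """Per-pixel LTriDP code; borders handled by replicate padding."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be 2D and at least 3x3, got {img.shape}")
    h, w = img.shape
    pad = np.pad(img, 1, mode="edge")
    neigh = [pad[1 + dr:1 + dr + h, 1 + dc:1 + dc + w] for dr, dc in NEIGHBOR_OFFSETS]
    bits = np.empty((h, w, 8), dtype=np.uint8)
    for t0 in range(8):
        p_prev = neigh[(t0 - 1) % 8]
        p_t = neigh[t0]
        p_next = neigh[(t0 + 1) % 8]
        m1 = (p_prev - img) ** 2 + (p_next - img) ** 2
        m2 = (p_prev - img) ** 2 + (p_next - p_t) ** 2
        bits[:, :, t0] = m1 >= m2
    weights = (1 << np.arange(8)).astype(np.uint16)
    code = (bits.astype(np.uint16) * weights).sum(axis=2).astype(np.uint8)
    return TextureMap(code=code, magnitude_bits=bits)


def count_histogram_peaks(
    img: np.ndarray,
    smooth_sigma: float = 5.0,
    prominence_frac: float = 0.01,
    k_max: int = 64,
) -> int:
    """Number of local maxima of the smoothed 256-bin intensity histogram.

    Peaks must exceed a prominence of ``prominence_frac`` of the pixel
    count.  Always returns at least 1.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    hist, _ = np.histogram(np.clip(img, 0, 255.999), bins=256, range=(0.0, 256.0))
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma, mode="constant")
    # Pad with zeros so maxima sitting on bin 0 or 255 are still detected.
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = find_peaks(padded, prominence=prominence_frac * img.size)
    return int(np.clip(len(peaks), 1, k_max))


def _init_centers(shape: tuple[int, int], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Regular-grid seeding of exactly ``k`` centers; returns (rows, cols)."""
    h, w = shape
    nr = max(1, round(math.sqrt(k * h / w)))
    nc = math.ceil(k / nr)
    while nr * nc < k:
        nc += 1
    rows = (np.arange(nr) + 0.5) * h / nr
    cols = (np.arange(nc) + 0.5) * w / nc
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr.ravel()[:k].copy(), cc.ravel()[:k].copy()


def slic_superpixels(
    img: np.ndarray,
    tex: TextureMap,
    K: int,
    iters: int = 10,
    ng: float = 255.0,
    nt: float = 255.0,
) -> LabelMap:
    """Texture-augmented SLIC with a restricted (Kim-style) center update.

    Pixels are assigned to the nearest of ``K`` grid-seeded centers inside a
    2S x 2S window (S = sqrt(P/K)) by the combined distance::

        D = sqrt((dg/ng)^2 + (dS/S)^2 + (dT/nt)^2)

    Center means are recomputed over the pixels whose gray value lies
    within one within-cluster standard deviation of the center gray value;
    if that set is empty the whole cluster is used.  Deterministic: no RNG,
    ties resolved toward the lowest center index.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    p_total = h * w
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > p_total:
        raise ValueError(f"K={K} exceeds the number of pixels {p_total}")
    texf = np.asarray(tex.code, dtype=float)
    s_len = math.sqrt(p_total / K)

    crow, ccol = _init_centers((h, w), K)
    cgray = img[np.clip(crow.astype(int), 0, h - 1), np.clip(ccol.astype(int), 0, w - 1)].copy()
    ctex = texf[np.clip(crow.astype(int), 0, h - 1), np.clip(ccol.astype(int), 0, w - 1)].copy()

    rows_grid, cols_grid = np.mgrid[0:h, 0:w]
    labels = np.full((h, w), -1, dtype=np.int32)

    def assign() -> np.ndarray:
        lab = np.full((h, w), -1, dtype=np.int32)
        best = np.full((h, w), np.inf)
        for k in range(K):
            r0 = max(0, int(math.floor(crow[k] - s_len)))
            r1 = min(h, int(math.ceil(crow[k] + s_len)) + 1)
            c0 = max(0, int(math.floor(ccol[k] - s_len)))
            c1 = min(w, int(math.ceil(ccol[k] + s_len)) + 1)
            sl = (slice(r0, r1), slice(c0, c1))
            dg = np.abs(img[sl] - cgray[k])
            ds = np.hypot(rows_grid[sl] - crow[k], cols_grid[sl] - ccol[k])
            dt = np.abs(texf[sl] - ctex[k])
            d = np.sqrt((dg / ng) ** 2 + (ds / s_len) ** 2 + (dt / nt) ** 2)
            better = d < best[sl]
            best[sl][better] = d[better]
            lab[sl][better] = k
        orphan = lab < 0
        if orphan.any():
            orows = rows_grid[orphan]
            ocols = cols_grid[orphan]
            og = img[orphan]
            ot = texf[orphan]
            d_all = np.sqrt(
                (np.abs(og[None, :] - cgray[:, None]) / ng) ** 2
                + (np.hypot(orows[None, :] - crow[:, None],
                            ocols[None, :] - ccol[:, None]) / s_len) ** 2
                + (np.abs(ot[None, :] - ctex[:, None]) / nt) ** 2
            )
            lab[orphan] = np.argmin(d_all, axis=0)
        return lab

    for _ in range(max(0, iters)):
        labels = assign()
        for k in range(K):
            member = labels == k
            if not member.any():
                continue
            g = img[member]
            sigma_k = g.std()
            near = np.abs(g - cgray[k]) < sigma_k
            if sigma_k == 0 or not near.any():
                near = np.ones(g.size, dtype=bool)
            cgray[k] = g[near].mean()
            crow[k] = rows_grid[member][near].mean()
            ccol[k] = cols_grid[member][near].mean()
            ctex[k] = texf[member][near].mean()
    labels = assign()

    # Guarantee every label is non-empty: hand the globally closest pixel
    # (by D) to each empty cluster, in increasing label order.
    counts = np.bincount(labels.ravel(), minlength=K)
    for k in np.nonzero(counts == 0)[0]:
        d = np.sqrt(
            (np.abs(img - cgray[k]) / ng) ** 2
            + (np.hypot(rows_grid - crow[k], cols_grid - ccol[k]) / s_len) ** 2
            + (np.abs(texf - ctex[k]) / nt) ** 2
        )
        # Only steal from clusters that keep at least 2 members.
        donor = np.bincount(labels.ravel(), minlength=K)[labels] >= 2
        d[~donor] = np.inf
        idx = np.unravel_index(np.argmin(d), d.shape)
        labels[idx] = k

    centers = {"gray": cgray, "row": crow, "col": ccol, "tex": ctex}
    return LabelMap(labels=labels, K=K, centers=centers)
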