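"""Independent brute-force oracles shared between unit and acceptance tests.

Everything here is deliberately naive (Counter-based histograms, explicit
loops, alternative LAPACK drivers) and stays independent of the package
code paths it is used to check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import scipy.linalg


def quantize_oracle(values: np.ndarray, bins: int) -> list[int]:
    """Bin indices for a 0-256 range histogram, computed pixel by pixel."""
    out = []
    for v in np.asarray(values, dtype=float).ravel():
        v = min(max(v, 0.0), 255.999)
        out.append(min(int(v * bins / 256.0), bins - 1))
    return out


def entropy_oracle(patch: np.ndarray, bins: int = 256) -> float:
    counts = Counter(quantize_oracle(patch, bins))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def joint_entropy_oracle(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    pairs = Counter(zip(quantize_oracle(a, bins), quantize_oracle(b, bins)))
    n = sum(pairs.values())
    return -sum((c / n) * math.log2(c / n) for c in pairs.values())


def mi_oracle(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    return (entropy_oracle(a, bins) + entropy_oracle(b, bins)
            - joint_entropy_oracle(a, b, bins))


def nmi_oracle(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    ha, hb = entropy_oracle(a, bins), entropy_oracle(b, bins)
    h_min = min(ha, hb)
    if h_min <= 0:
        if ha == 0 and hb == 0:
            return 1.0 if float(np.ravel(a)[0]) == float(np.ravel(b)[0]) else 0.0
        return 0.0
    return min(max(mi_oracle(a, b, bins) / h_min, 0.0), 1.0)


def svd_soft_threshold_oracle(matrix: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Reconstruction via scipy's gesvd driver (distinct from numpy's gesdd)."""
    u, s, vt = scipy.linalg.svd(np.asarray(matrix, dtype=float),
                                full_matrices=False, lapack_driver="gesvd")
    out = np.zeros_like(matrix, dtype=float)
    for i in range(len(s)):
        shrunk = max(s[i] - w[i], 0.0)
        out += shrunk * np.outer(u[:, i], vt[i, :])
    return out


def destensorize_oracle(groups, shape, fallback=None) -> np.ndarray:
    """Per-pixel accumulation with explicit python loops."""
    h, w = shape
    out = np.zeros(shape)
    for i in range(h):
        for j in range(w):
            num = den = plain = cnt = 0.0
            for g in groups:
                n = g.tensor.shape[0]
                for m, (r0, c0) in enumerate(g.origins):
                    if r0 <= i < r0 + n and c0 <= j < c0 + n:
                        q = 1.0 if m == 0 else max(0.0, 1.0 - g.mi_scores[m])
                        v = g.tensor[i - r0, j - c0, m]
                        num += q * v
                        den += q
                        plain += v
                        cnt += 1
            if den > 1e-12:
                out[i, j] = num / den
            elif cnt > 0:
                out[i, j] = plain / cnt
            elif fallback is not None:
                out[i, j] = fallback[i, j]
    return out


def speckle_index_oracle(img, mask) -> float:
    vals = [float(img[i, j]) for i in range(img.shape[0])
            for j in range(img.shape[1]) if mask[i, j]]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return math.sqrt(var) / mean


def smpi_oracle(noisy, despeckled, mask) -> float:
    xn = [float(noisy[i, j]) for i in range(noisy.shape[0])
          for j in range(noisy.shape[1]) if mask[i, j]]
    xd = [float(despeckled[i, j]) for i in range(noisy.shape[0])
          for j in range(noisy.shape[1]) if mask[i, j]]
    n = len(xn)
    mean_n = sum(xn) / n
    mean_d = sum(xd) / n
    std_n = math.sqrt(sum((v - mean_n) ** 2 for v in xn) / n)
    std_d = math.sqrt(sum((v - mean_d) ** 2 for v in xd) / n)
    r = (max(xd) - min(xd)) / mean_n
    return (r + abs(mean_n - mean_d)) * std_d / std_n


def mse_psnr_oracle(ground, test) -> tuple[float, float]:
    h, w = ground.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            total += (float(ground[i, j]) - float(test[i, j])) ** 2
    mse = total / (h * w)
    psnr = float("inf") if mse == 0 else 10.0 * math.log10(255.0**2 / mse)
    return mse, psnr


def laplacian_oracle(img: np.ndarray) -> np.ndarray:
    """3x3 Laplacian with replicate borders, explicit loops."""
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            up = img[max(i - 1, 0), j]
            down = img[min(i + 1, h - 1), j]
            left = img[i, max(j - 1, 0)]
            right = img[i, min(j + 1, w - 1)]
            out[i, j] = up + down + left + right - 4.0 * img[i, j]
    return out


def epi_oracle(ground, test) -> float:
    hg = laplacian_oracle(np.asarray(ground, dtype=float))
    hd = laplacian_oracle(np.asarray(test, dtype=float))
    hg = hg - hg.mean()
    hd = hd - hd.mean()
    num = 0.0
    sg = sd = 0.0
    for i in range(hg.shape[0]):
        for j in range(hg.shape[1]):
            num += hg[i, j] * hd[i, j]
            sg += hg[i, j] ** 2
            sd += hd[i, j] ** 2
    corr = num / math.sqrt(sg * sd)
    return min(max(corr, 0.0), 1.0)


def resolution_alpha_oracle(img: np.ndarray) -> float:
    """Autocorrelation via explicit circular shifts (no FFT)."""
    x = np.asarray(img, dtype=float)
    x = x - x.mean()
    h, w = x.shape
    acf = np.zeros((h, w))
    for di in range(h):
        for dj in range(w):
            acf[di, dj] = float((x * np.roll(np.roll(x, di, axis=0), dj, axis=1)).sum())
    acf /= acf.max()
    return float((acf > 0.75).sum()) / (h * w)


def ltridp_bits_oracle(img: np.ndarray, i: int, j: int) -> list[int]:
    """Magnitude bits at one pixel, from the raw formulas with explicit
    replicate padding; neighbor order clockwise from the top-left."""
    h, w = img.shape

    def px(r, c):
        return float(img[min(max(r, 0), h - 1), min(max(c, 0), w - 1)])

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    pc = px(i, j)
    p = [px(i + dr, j + dc) for dr, dc in offsets]
    bits = []
    for t in range(8):
        p_prev = p[(t - 1) % 8]
        p_t = p[t]
        p_next = p[(t + 1) % 8]
        m1 = (p_prev - pc) ** 2 + (p_next - pc) ** 2
        m2 = (p_prev - pc) ** 2 + (p_next - p_t) ** 2
        bits.append(1 if m1 >= m2 else 0)
    return bits
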