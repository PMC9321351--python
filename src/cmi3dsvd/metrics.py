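"""Despeckling quality metrics.

Non-reference metrics (SI, SSI, SMPI) are evaluated over an explicit
homogeneous region of interest; full-reference metrics (MSE/PSNR, SSIM,
EPI) compare against a noise-free ground truth; resolution alpha measures
the spread of the image autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity

__all__ = [
    "MetricsReport",
    "roi_mask",
    "speckle_index",
    "ssi",
    "smpi",
    "mse_psnr",
    "ssim",
    "epi",
    "resolution_alpha",
    "evaluate_all",
]

PEAK = 255.0

LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0],
                             [1.0, -4.0, 1.0],
                             [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class MetricsReport:
    si: Optional[float] = None
    ssi: Optional[float] = None
    smpi: Optional[float] = None
    mse: Optional[float] = None
    psnr: Optional[float] = None
    ssim: Optional[float] = None
    epi: Optional[float] = None
    alpha: Optional[float] = None
    roi: Optional[tuple[int, int, int, int]] = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("si", "ssi", "smpi", "mse", "psnr", "ssim", "epi", "alpha")}
        if self.roi is not None:
            d["roi"] = list(self.roi)
        return d


def roi_mask(shape: tuple[int, int], roi) -> np.ndarray:
    """Boolean mask from either a mask array or a half-open rectangle.

    Rectangles are ``(r0, c0, r1, c1)`` with exclusive ends.
    """
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool and roi_arr.shape == shape:
        mask = roi_arr
    elif roi_arr.shape == (4,):
        r0, c0, r1, c1 = (int(v) for v in roi_arr)
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError(f"rectangle {roi} out of bounds for shape {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
    else:
        raise ValueError("roi must be a boolean mask or a (r0, c0, r1, c1) rectangle")
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def _roi_values(img: np.ndarray, roi) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img[roi_mask(img.shape, roi)]


def speckle_index(img: np.ndarray, roi=None) -> float:
    """SI = std / mean over the ROI."""
    v = _roi_values(img, roi)
    mean = v.mean()
    if mean == 0:
        raise ValueError("speckle index undefined: zero mean over the ROI")
    return float(v.std() / mean)


def ssi(noisy: np.ndarray, despeckled: np.ndarray, roi=None) -> float:
    """Speckle suppression index: SI(despeckled) / SI(noisy). Lower is better."""
    si_noisy = speckle_index(noisy, roi)
    if si_noisy == 0:
        raise ValueError("SSI undefined: noisy ROI has zero variance")
    return float(speckle_index(despeckled, roi) / si_noisy)


def smpi(noisy: np.ndarray, despeckled: np.ndarray, roi=None) -> float:
    """Speckle suppression and mean preservation index (lower is better).

    ``SMPI = (R + |E[Xn] - E[Xd]|) * std(Xd) / std(Xn)`` with
    ``R = (max(Xd) - min(Xd)) / E[Xn]``, extrema taken over the ROI pixels.
    """
    xn = _roi_values(noisy, roi)
    xd = _roi_values(despeckled, roi)
    if xn.std() == 0:
        raise ValueError("SMPI undefined: noisy ROI has zero variance")
    if xn.mean() == 0:
        raise ValueError("SMPI undefined: noisy ROI has zero mean")
    r = (xd.max() - xd.min()) / xn.mean()
    return float((r + abs(xn.mean() - xd.mean())) * xd.std() / xn.std())


def mse_psnr(ground: np.ndarray, test: np.ndarray) -> tuple[float, float]:
    """Mean squared error and peak SNR in dB (peak 255; inf for identity)."""
    g = np.asarray(ground, dtype=float)
    t = np.asarray(test, dtype=float)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    mse = float(np.mean((g - t) ** 2))
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(PEAK**2 / mse))
    return mse, psnr


def ssim(ground: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity with the canonical Gaussian 11x11 window."""
    g = np.asarray(ground, dtype=float)
    t = np.asarray(test, dtype=float)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    return float(structural_similarity(
        g, t, data_range=PEAK, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


def epi(ground: np.ndarray, test: np.ndarray) -> float:
    """Edge preservation index: correlation of mean-centered Laplacians.

    Clipped to [0, 1]; a negative correlation is reported as 0 with a
    warning.  Raises on images whose Laplacian response is constant.
    """
    g = np.asarray(ground, dtype=float)
    t = np.asarray(test, dtype=float)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {t.shape}")
    hg = convolve(g, LAPLACIAN_KERNEL, mode="nearest")
    hd = convolve(t, LAPLACIAN_KERNEL, mode="nearest")
    hg = hg - hg.mean()
    hd = hd - hd.mean()
    denom = np.sqrt((hg**2).sum() * (hd**2).sum())
    if denom == 0:
        raise ValueError("EPI undefined: constant Laplacian response")
    corr = float((hg * hd).sum() / denom)
    if corr < 0:
        warnings.warn(f"negative edge correlation {corr:.4f} clipped to 0")
        return 0.0
    return min(corr, 1.0)


def resolution_alpha(img: np.ndarray) -> float:
    """Fraction of the normalized autocorrelation above 75% of its peak.

    The mean is removed before the FFT autocorrelation so the measure is
    invariant to intensity offset and scale; lower alpha = finer detail.
    """
    x = np.asarray(img, dtype=float)
    x = x - x.mean()
    if np.all(x == 0):
        raise ValueError("resolution alpha undefined for a constant image")
    f = np.fft.fft2(x)
    acf = np.real(np.fft.ifft2(f * np.conj(f)))
    acf /= acf.max()
    return float(np.count_nonzero(acf > 0.75) / acf.size)


def evaluate_all(
    despeckled: np.ndarray,
    noisy: np.ndarray | None = None,
    ground: np.ndarray | None = None,
    roi=None,
) -> MetricsReport:
    """All metrics that the available inputs permit, as one report."""
    kw: dict = {}
    kw["si"] = speckle_index(despeckled, roi)
    kw["alpha"] = resolution_alpha(despeckled)
    if noisy is not None:
        kw["ssi"] = ssi(noisy, despeckled, roi)
        kw["smpi"] = smpi(noisy, despeckled, roi)
    if ground is not None:
        kw["mse"], kw["psnr"] = mse_psnr(ground, despeckled)
        kw["ssim"] = ssim(ground, despeckled)
        kw["epi"] = epi(ground, despeckled)
    if roi is not None and np.asarray(roi).shape == (4,):
        kw["roi"] = tuple(int(v) for v in np.asarray(roi))
    return MetricsReport(**kw)
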