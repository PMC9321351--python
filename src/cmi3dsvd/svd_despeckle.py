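"""Log-domain low-rank despeckling of patch groups and re-aggregation.

Each patch group is log-transformed (turning multiplicative speckle into
additive noise), unfolded into an (n^2) x k matrix with patches as columns,
and denoised by SVD soft-thresholding with weighted-nuclear-norm weights::

    w_i = r * sqrt(k) * sigma^2 / (sqrt(max(s_i^2 - k * sigma^2, 0)) + eps)

so strong (signal) singular values are barely touched while noise-level
ones are suppressed.  Groups are folded back, exponentiated, and
re-aggregated into an image by a per-pixel weighted average whose weights
derive from the match scores (``q_m = 1 - NMI``; the reference slice keeps
weight 1).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .block_matching import PatchGroup

__all__ = [
    "LogGroup",
    "ShrinkageWeights",
    "log_transform",
    "exp_transform",
    "estimate_sigma_log",
    "shrinkage_weights",
    "svd_soft_threshold",
    "despeckle_group",
    "destensorize",
]

EPSILON = 1e-16

#: Default weight scale ``r`` (> 0, exposed in every config surface).
DEFAULT_R = 1.0

#: Default offset added before the log transform so zero-valued (cyst)
#: pixels stay finite; subtracted back after exponentiation.
DEFAULT_LOG_OFFSET = 1.0


@dataclass(frozen=True)
class LogGroup:
    """(n^2) x k unfolding of a log-transformed group (patches as columns)."""

    matrix: np.ndarray = field(repr=False)
    sigma_log: float
    k: int
    patch_size: int
    offset: float


@dataclass(frozen=True)
class ShrinkageWeights:
    """Per-singular-value soft-threshold amounts."""

    w: np.ndarray = field(repr=False)
    r: float
    epsilon: float = EPSILON


def _unfold(tensor: np.ndarray) -> np.ndarray:
    """Column-major vectorization of each slice: (n, n, k) -> (n^2, k)."""
    n = tensor.shape[0]
    return tensor.reshape(n * n, tensor.shape[2], order="F")


def _fold(matrix: np.ndarray, n: int) -> np.ndarray:
    return matrix.reshape(n, n, matrix.shape[1], order="F")


def log_transform(group: PatchGroup, offset: float = DEFAULT_LOG_OFFSET,
                  sigma_log: float = 0.0) -> LogGroup:
    """Unfold a group and map intensities through ``ln(x + offset)``."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    t = np.asarray(group.tensor, dtype=float)
    if (t < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    if offset == 0 and (t == 0).any():
        raise ValueError("offset must be positive when zeros are present")
    return LogGroup(
        matrix=np.log(_unfold(t) + offset),
        sigma_log=float(sigma_log),
        k=group.k,
        patch_size=group.patch_size,
        offset=float(offset),
    )


def exp_transform(log_group: LogGroup) -> np.ndarray:
    """Inverse of :func:`log_transform`: returns the (n, n, k) tensor."""
    t = np.exp(log_group.matrix) - log_group.offset
    return _fold(np.maximum(t, 0.0), log_group.patch_size)


@functools.lru_cache(maxsize=None)
def estimate_sigma_log(sigma_speckle: float, floor: float = 1e-2,
                       n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Std of ``ln(max(1 + sigma * G, floor))`` by fixed-seed Monte Carlo.

    This is the additive-noise level seen in the log domain by a pixel with
    unit clean intensity; for small sigma it approaches sigma itself.  The
    ``floor`` models the clamping effect of the log offset relative to a
    typical intensity scale.  Deterministic (fixed seed), cached.
    """
    if sigma_speckle < 0:
        raise ValueError("sigma_speckle must be non-negative")
    if sigma_speckle == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_samples)
    vals = np.log(np.maximum(1.0 + sigma_speckle * g, floor))
    return float(vals.std())


def shrinkage_weights(singular_values: np.ndarray, sigma_log: float,
                      k: int, r: float = DEFAULT_R) -> ShrinkageWeights:
    """Weighted-nuclear-norm thresholds for a descending spectrum."""
    s = np.asarray(singular_values, dtype=float)
    if (s < 0).any() or sigma_log < 0 or k < 1 or r <= 0:
        raise ValueError("singular values and sigma_log must be >= 0, k >= 1, r > 0")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("singular values must be sorted in descending order")
    clean_est = np.sqrt(np.maximum(s**2 - k * sigma_log**2, 0.0))
    w = r * np.sqrt(k) * sigma_log**2 / (clean_est + EPSILON)
    return ShrinkageWeights(w=w, r=float(r))


def svd_soft_threshold(matrix: np.ndarray, weights: ShrinkageWeights) -> np.ndarray:
    """``U diag(max(s - w, 0)) V^T`` of the input's SVD."""
    m = np.asarray(matrix, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    s_shrunk = np.maximum(s - weights.w, 0.0)
    return (u * s_shrunk) @ vt


def despeckle_group(group: PatchGroup, sigma_speckle: float,
                    r: float = DEFAULT_R,
                    offset: float = DEFAULT_LOG_OFFSET,
                    sigma_log: float | None = None) -> PatchGroup:
    """Full per-group pipeline: log -> SVD shrinkage -> exp.

    ``sigma_log`` may be supplied (e.g. a per-cluster estimate); otherwise
    it is derived from ``sigma_speckle`` via :func:`estimate_sigma_log`.
    Group geometry (origins, scores, cluster id) is preserved.
    """
    if sigma_log is None:
        sigma_log = estimate_sigma_log(float(sigma_speckle))
    lg = log_transform(group, offset=offset, sigma_log=sigma_log)
    s = np.linalg.svd(lg.matrix, compute_uv=False)
    weights = shrinkage_weights(s, sigma_log=lg.sigma_log, k=lg.k, r=r)
    denoised = svd_soft_threshold(lg.matrix, weights)
    tensor = exp_transform(LogGroup(denoised, lg.sigma_log, lg.k,
                                    lg.patch_size, lg.offset))
    return PatchGroup(
        tensor=tensor,
        origins=group.origins,
        mi_scores=group.mi_scores,
        cluster_id=group.cluster_id,
    )


def destensorize(groups: list[PatchGroup], shape: tuple[int, int],
                 fallback: np.ndarray | None = None) -> np.ndarray:
    """Weighted re-aggregation of group slices into a single image.

    Slice m of each group contributes with weight ``q_m = 1 - NMI`` to every
    pixel of its footprint; the reference slice (m = 0) contributes with
    weight 1.  Covered pixels whose total weight vanishes fall back to the
    unweighted mean of their covering slices; pixels covered by no group
    are copied from ``fallback`` (with a warning) or left at 0.
    """
    num = np.zeros(shape)
    den = np.zeros(shape)
    plain_sum = np.zeros(shape)
    count = np.zeros(shape)
    for g in groups:
        n = g.patch_size
        for m, (r0, c0) in enumerate(g.origins):
            q = 1.0 if m == 0 else max(0.0, 1.0 - g.mi_scores[m])
            sl = (slice(r0, r0 + n), slice(c0, c0 + n))
            patch = g.tensor[:, :, m]
            num[sl] += q * patch
            den[sl] += q
            plain_sum[sl] += patch
            count[sl] += 1.0

    out = np.zeros(shape)
    weighted = den > 1e-12
    out[weighted] = num[weighted] / den[weighted]
    degenerate = ~weighted & (count > 0)
    if degenerate.any():
        out[degenerate] = plain_sum[degenerate] / count[degenerate]
    uncovered = count == 0
    if uncovered.any():
        warnings.warn(f"{int(uncovered.sum())} pixels covered by no group")
        if fallback is not None:
            out[uncovered] = np.asarray(fallback, dtype=float)[uncovered]
    return out
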