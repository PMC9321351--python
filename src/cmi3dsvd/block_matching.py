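"""Mutual-information block matching within superpixel clusters.

Patch similarity is the plug-in mutual information of the patches' intensity
histograms, ``MI(a, b) = H(a) + H(b) - H(a, b)``, normalized by the smaller
marginal entropy so scores live in [0, 1].  For every reference patch tiled
over a cluster, candidates whose centers lie in the same cluster are ranked
by normalized MI and stacked into an n x n x k tensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Patch",
    "PatchGroup",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "normalized_mi",
    "group_patches",
]

_EPS = 1e-16


@dataclass(frozen=True)
class Patch:
    """An n x n crop with its top-left corner in image coordinates (0-based)."""

    pixels: np.ndarray = field(repr=False)
    origin: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class PatchGroup:
    """Stack of similar patches; slice 0 along the last axis is the reference."""

    tensor: np.ndarray = field(repr=False)   # (n, n, k)
    origins: tuple[tuple[int, int], ...]
    mi_scores: tuple[float, ...]             # normalized MI vs reference; [0] == 1
    cluster_id: int = 0

    @property
    def k(self) -> int:
        return self.tensor.shape[2]

    @property
    def patch_size(self) -> int:
        return self.tensor.shape[0]


def _pixels(p) -> np.ndarray:
    return np.asarray(getattr(p, "pixels", p), dtype=float)


def entropy(patch, bins: int = 256) -> float:
    """Shannon entropy (bits) of the patch intensity histogram."""
    a = _pixels(patch)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    hist, _ = np.histogram(np.clip(a, 0, 255.999), bins=bins, range=(0.0, 256.0))
    p = hist[hist > 0] / a.size
    return float(-(p * np.log2(p)).sum())


def joint_entropy(a, b, bins: int = 256) -> float:
    """Joint entropy (bits) of co-located pixel pairs of two same-shape patches."""
    av, bv = _pixels(a), _pixels(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    hist, _, _ = np.histogram2d(
        np.clip(av, 0, 255.999).ravel(),
        np.clip(bv, 0, 255.999).ravel(),
        bins=bins,
        range=[[0.0, 256.0], [0.0, 256.0]],
    )
    p = hist[hist > 0] / av.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(a, b, bins: int = 256) -> float:
    """``MI(a, b) = H(a) + H(b) - H(a, b)`` in bits."""
    return entropy(a, bins) + entropy(b, bins) - joint_entropy(a, b, bins)


def normalized_mi(a, b, bins: int = 256) -> float:
    """Mutual information normalized to [0, 1] by the smaller marginal entropy.

    Degenerate cases: two constant patches score 1 if their constants are
    equal and 0 otherwise; a single constant patch always scores 0.
    """
    av, bv = _pixels(a), _pixels(b)
    ha, hb = entropy(av, bins), entropy(bv, bins)
    h_min = min(ha, hb)
    if h_min <= 0.0:
        if ha == 0.0 and hb == 0.0:
            return 1.0 if float(av.flat[0]) == float(bv.flat[0]) else 0.0
        return 0.0
    mi = ha + hb - joint_entropy(av, bv, bins)
    return float(np.clip(mi / max(_EPS, h_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Vectorized grouping machinery


def _quantize(img: np.ndarray, bins: int) -> np.ndarray:
    """Bin indices matching np.histogram(..., bins, range=(0, 256))."""
    q = np.floor(np.clip(img, 0, 255.999) * (bins / 256.0)).astype(np.int64)
    return np.minimum(q, bins - 1)


def _row_entropies(codes: np.ndarray, n_rows: int, span: int) -> np.ndarray:
    """Entropy (bits) of each row of an integer matrix with values < span."""
    m, n = codes.shape
    flat = (codes + np.arange(m, dtype=np.int64)[:, None] * span).ravel()
    uq, cnt = np.unique(flat, return_counts=True)
    rows = uq // span
    p = cnt / n
    h = np.zeros(m)
    np.add.at(h, rows, -p * np.log2(p))
    return h


def group_patches(
    img: np.ndarray,
    labels,
    cluster_id: int,
    patch_size: int = 5,
    k_max: int = 16,
    nmi_threshold: float = 0.3,
    stride: int | None = None,
    bins: int = 256,
    search_radius: int | None = None,
) -> list[PatchGroup]:
    """Build MI-ranked patch groups covering one cluster.

    Reference patches are tiled over the cluster at ``stride`` (default
    ``patch_size - 1``, snapping the last tile to the cluster boundary).
    Candidates are all patch positions whose center pixel carries
    ``cluster_id``; with ``search_radius`` set, only candidates within that
    Chebyshev distance (in origin coordinates) of the reference are
    considered — exhaustive search over the whole cluster otherwise.
    Candidates with normalized MI >= ``nmi_threshold`` are kept, ranked by
    NMI descending with ties broken by (row, col), truncated so the group
    holds at most ``k_max`` slices including the reference.  Any cluster
    pixel left uncovered by the tiling gets an extra (edge-snapped) group.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    n = int(patch_size)
    if n < 3 or n % 2 == 0:
        raise ValueError("patch_size must be odd and >= 3")
    if h < n or w < n:
        raise ValueError(f"image {img.shape} smaller than patch {n}x{n}")
    if k_max < 1 or (stride is not None and stride < 1):
        raise ValueError("k_max and stride must be >= 1")
    stride = stride if stride is not None else max(1, n - 1)
    half = n // 2

    lab_arr = getattr(labels, "labels", labels)
    if lab_arr is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(lab_arr) == cluster_id
    if not mask.any():
        warnings.warn(f"cluster {cluster_id} is empty; no groups built")
        return []

    nrow, ncol = h - n + 1, w - n + 1  # valid origin grid
    q = _quantize(img, bins)
    win = np.lib.stride_tricks.sliding_window_view(img, (n, n))
    qwin = np.lib.stride_tricks.sliding_window_view(q, (n, n))
    qflat = qwin.reshape(nrow * ncol, n * n)

    # Marginal entropy of every candidate position, computed once.
    h_marg = _row_entropies(qflat, nrow * ncol, bins).reshape(nrow, ncol)

    cand_ok = mask[half:half + nrow, half:half + ncol]  # center-in-cluster rule

    def snapped_range(lo: int, hi: int) -> list[int]:
        vals = list(range(lo, hi + 1, stride))
        if vals[-1] != hi:
            vals.append(hi)
        return vals

    rows_any = np.nonzero(mask.any(axis=1))[0]
    cols_any = np.nonzero(mask.any(axis=0))[0]
    r_lo = int(np.clip(rows_any[0] - half, 0, nrow - 1))
    r_hi = int(np.clip(rows_any[-1] - half, 0, nrow - 1))
    c_lo = int(np.clip(cols_any[0] - half, 0, ncol - 1))
    c_hi = int(np.clip(cols_any[-1] - half, 0, ncol - 1))

    ref_origins = [
        (r, c)
        for r in snapped_range(r_lo, r_hi)
        for c in snapped_range(c_lo, c_hi)
        if cand_ok[r, c]
    ]

    span = bins * bins

    def build_group(r: int, c: int) -> PatchGroup:
        if search_radius is None:
            wr0, wr1, wc0, wc1 = 0, nrow, 0, ncol
        else:
            wr0 = max(0, r - search_radius)
            wr1 = min(nrow, r + search_radius + 1)
            wc0 = max(0, c - search_radius)
            wc1 = min(ncol, c + search_radius + 1)
        sub = cand_ok[wr0:wr1, wc0:wc1]
        rr, cc = np.nonzero(sub)
        rr = rr + wr0
        cc = cc + wc0
        self_idx = (rr == r) & (cc == c)
        rr, cc = rr[~self_idx], cc[~self_idx]

        ref_q = qflat[r * ncol + c]
        h_ref = h_marg[r, c]
        if rr.size:
            cand_q = qflat[rr * ncol + cc]
            h_joint = _row_entropies(ref_q[None, :] * bins + cand_q, rr.size, span)
            h_cand = h_marg[rr, cc]
            mi = h_ref + h_cand - h_joint
            h_min = np.minimum(h_ref, h_cand)
            with np.errstate(invalid="ignore", divide="ignore"):
                nmi = np.clip(mi / np.maximum(_EPS, h_min), 0.0, 1.0)
            degenerate = h_min <= 0.0
            if degenerate.any():
                both_const = degenerate & (h_ref <= 0.0) & (h_cand <= 0.0)
                nmi[degenerate] = 0.0
                nmi[both_const & (cand_q[:, 0] == ref_q[0])] = 1.0
            # rank on NMI rounded to 1e-9 so ordering is stable against
            # summation-order rounding noise; ties break by (row, col)
            order = np.lexsort((cc, rr, -np.round(nmi, 9)))
            order = order[nmi[order] >= nmi_threshold][: k_max - 1]
            rr, cc, nmi = rr[order], cc[order], nmi[order]
        else:
            nmi = np.empty(0)

        origins = [(r, c)] + [(int(a), int(b)) for a, b in zip(rr, cc)]
        tensor = np.stack([win[a, b] for a, b in origins], axis=-1)
        scores = (1.0,) + tuple(float(v) for v in nmi)
        return PatchGroup(
            tensor=np.ascontiguousarray(tensor),
            origins=tuple(origins),
            mi_scores=scores,
            cluster_id=int(cluster_id),
        )

    groups = [build_group(r, c) for r, c in ref_origins]

    # Coverage repair: every cluster pixel must fall under at least one
    # patch footprint; uncovered pixels seed extra edge-snapped groups.
    covered = np.zeros((h, w), dtype=bool)
    for g in groups:
        for (a, b) in g.origins:
            covered[a:a + n, b:b + n] = True
    missing = mask & ~covered
    while missing.any():
        pr, pc = np.argwhere(missing)[0]
        r = int(np.clip(pr - half, 0, nrow - 1))
        c = int(np.clip(pc - half, 0, ncol - 1))
        g = build_group(r, c)
        groups.append(g)
        for (a, b) in g.origins:
            covered[a:a + n, b:b + n] = True
        missing = mask & ~covered

    return groups
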