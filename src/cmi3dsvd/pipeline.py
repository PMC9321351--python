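"""End-to-end despeckling pipeline and benchmark harness.

Stages: LTriDP texture + superpixel segmentation -> per-cluster MI block
matching -> log-domain SVD shrinkage -> weighted re-aggregation -> guided
bilateral post-filter.  The filter itself is deterministic; all randomness
lives in the speckle simulator.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import block_matching, segmentation, svd_despeckle
from .postprocess import GabfParams, gabf
from .speckle_sim import apply_speckle
from . import metrics as metrics_mod

__all__ = [
    "PipelineConfig",
    "RunLog",
    "resolve_patch_size",
    "despeckle_image",
    "run_benchmark",
    "benchmark_to_csv",
]

#: Noise levels below this use 5x5 patches, above it 7x7 ("auto" rule).
PATCH_RULE_SIGMA = 0.50


@dataclass
class PipelineConfig:
    sigma: float = 0.2
    patch_size: int | str = "auto"      # "auto" | 5 | 7 | any odd size
    nmi_threshold: float = 0.3
    k_max: int = 16
    stride: Optional[int] = None        # default: patch_size - 1
    search_radius: Optional[int] = 12   # Chebyshev, in origin coordinates
    bins: int = 256
    slic_iters: int = 10
    K: Optional[int] = None             # cluster-count override
    r: float = svd_despeckle.DEFAULT_R
    log_offset: float = svd_despeckle.DEFAULT_LOG_OFFSET
    gabf: GabfParams = field(default_factory=GabfParams)
    postprocess: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.patch_size != "auto":
            p = int(self.patch_size)
            if p < 3 or p % 2 == 0:
                raise ValueError("patch_size must be odd and >= 3, or 'auto'")

    def resolved_patch_size(self) -> int:
        if self.patch_size == "auto":
            return resolve_patch_size(self.sigma)
        return int(self.patch_size)


@dataclass
class RunLog:
    config: dict
    K: int = 0
    n_groups: int = 0
    mean_group_depth: float = 0.0
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)


def resolve_patch_size(sigma: float) -> int:
    """5x5 for sigma <= 0.50, 7x7 beyond."""
    return 5 if sigma <= PATCH_RULE_SIGMA else 7


def despeckle_image(img: np.ndarray, cfg: PipelineConfig | None = None
                    ) -> tuple[np.ndarray, RunLog]:
    """Run the full filter on a single grayscale image (0-255 scale)."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError(f"expected a 2D image of at least 3x3, got {img.shape}")
    patch = cfg.resolved_patch_size()
    log = RunLog(config={**asdict(cfg), "resolved_patch_size": patch})
    tic = time.perf_counter

    t0 = tic()
    tiny = min(img.shape) < 2 * patch
    if tiny:
        labels = segmentation.LabelMap(
            labels=np.zeros(img.shape, dtype=np.int32), K=1,
            centers={"gray": np.array([img.mean()]),
                     "row": np.array([img.shape[0] / 2]),
                     "col": np.array([img.shape[1] / 2]),
                     "tex": np.array([0.0])})
        log.warnings.append("image smaller than 2x patch size: single-cluster fallback")
    else:
        tex = segmentation.ltridp_map(img)
        k_clusters = cfg.K if cfg.K is not None else segmentation.count_histogram_peaks(img)
        labels = segmentation.slic_superpixels(img, tex, k_clusters, iters=cfg.slic_iters)
    log.K = labels.K
    log.timings["segment"] = tic() - t0

    if min(img.shape) < patch:
        raise ValueError(f"image {img.shape} smaller than patch size {patch}")

    t0 = tic()
    groups = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for cid in range(labels.K):
            groups.extend(block_matching.group_patches(
                img, labels, cid,
                patch_size=patch, k_max=cfg.k_max,
                nmi_threshold=cfg.nmi_threshold, stride=cfg.stride,
                bins=cfg.bins, search_radius=cfg.search_radius,
            ))
    log.warnings.extend(str(c.message) for c in caught)
    log.n_groups = len(groups)
    log.mean_group_depth = float(np.mean([g.k for g in groups])) if groups else 0.0
    log.timings["match"] = tic() - t0

    t0 = tic()
    sigma_log = svd_despeckle.estimate_sigma_log(float(cfg.sigma))
    despeckled_groups = [
        svd_despeckle.despeckle_group(g, cfg.sigma, r=cfg.r,
                                      offset=cfg.log_offset, sigma_log=sigma_log)
        for g in groups
    ]
    log.timings["shrink"] = tic() - t0

    t0 = tic()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        out = svd_despeckle.destensorize(despeckled_groups, img.shape, fallback=img)
    log.warnings.extend(str(c.message) for c in caught)
    out = np.clip(out, 0.0, 255.0)
    log.timings["aggregate"] = tic() - t0

    if cfg.postprocess:
        t0 = tic()
        out = np.clip(gabf(out, cfg.gabf), 0.0, 255.0)
        log.timings["postprocess"] = tic() - t0

    if not np.isfinite(out).all():
        raise RuntimeError("pipeline produced non-finite pixels")
    return out, log


def run_benchmark(
    clean: np.ndarray,
    sigmas,
    reps: int = 10,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    roi=None,
    seeds=None,
) -> dict:
    """Speckle -> despeckle -> metrics, averaged over ``reps`` seeded runs.

    Returns ``{sigma: {metric: mean value}}``; full-reference metrics are
    computed against ``clean``, the SSI/SMPI pair against the noisy input
    over ``roi`` (whole image if omitted).  Per-rep noise seeds default to
    ``seed + rep``; an explicit ``seeds`` list (length ``reps``) overrides.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seeds is not None and len(seeds) != reps:
        raise ValueError("seeds must have one entry per rep")
    clean = np.asarray(clean, dtype=float)
    base_cfg = cfg or PipelineConfig()
    table: dict = {}
    for sigma in sigmas:
        run_cfg = PipelineConfig(**{**asdict(base_cfg), "sigma": float(sigma)})
        if isinstance(run_cfg.gabf, dict):
            run_cfg.gabf = GabfParams(**run_cfg.gabf)
        acc: dict[str, list[float]] = {}
        for rep in range(reps):
            rep_seed = seeds[rep] if seeds is not None else seed + rep
            noisy = apply_speckle(clean, float(sigma), seed=rep_seed)
            out, _ = despeckle_image(noisy, run_cfg)
            report = metrics_mod.evaluate_all(out, noisy=noisy, ground=clean, roi=roi)
            for name, value in report.to_dict().items():
                if name == "roi" or value is None:
                    continue
                acc.setdefault(name, []).append(float(value))
        table[float(sigma)] = {name: float(np.mean(vals)) for name, vals in acc.items()}
    return table


def benchmark_to_csv(table: dict) -> str:
    """Render a benchmark table as CSV: rows = metrics, columns = sigma."""
    sigmas = sorted(table)
    names = sorted({name for col in table.values() for name in col})
    lines = ["metric," + ",".join(f"{s:g}" for s in sigmas)]
    for name in names:
        cells = [f"{table[s].get(name, float('nan')):.6g}" for s in sigmas]
        lines.append(name + "," + ",".join(cells))
    return "\n".join(lines) + "\n"
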