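"""Synthetic cyst phantoms and multiplicative speckle injection.

The speckle model is ``X = Y * S + A`` where ``Y`` is the noise-free image,
``S`` a unit-mean multiplicative field and ``A`` an optional low-amplitude
additive term.  Two speckle generators are provided:

* :func:`apply_speckle` — parametric model ``S = 1 + sigma * G`` with ``G``
  standard normal, clipped below at zero, for standard-deviation sweeps.
* :func:`rayleigh_speckle` — unit-mean Rayleigh amplitude field, the
  fully-developed-speckle statistic expected in homogeneous regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Disc",
    "PhantomSpec",
    "SpeckleField",
    "generate_phantom",
    "rayleigh_speckle",
    "apply_speckle",
    "default_phantom_spec",
    "homogeneous_roi",
]

#: Width (pixels) of the smooth taper ring placed just outside every
#: phantom region, so region interiors keep their exact nominal amplitude.
TAPER_WIDTH = 2.0

#: Coefficient of variation (std/mean) of a Rayleigh amplitude field.
RAYLEIGH_CV = float(np.sqrt(4.0 / np.pi - 1.0))

#: Amplitude multiplier of high-scattering (bright) regions.
BRIGHT_GAIN = 10.0


@dataclass(frozen=True)
class Disc:
    """A disc region given by a (row, col) center and a radius in pixels."""

    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a cyst phantom.

    ``cyst_regions`` are anechoic (zero amplitude) discs, ``bright_regions``
    are high-scattering discs at ``BRIGHT_GAIN`` times the background mean.
    """

    shape: tuple[int, int]
    cyst_regions: tuple[Disc, ...] = ()
    bright_regions: tuple[Disc, ...] = ()
    background_mean: float = 100.0

    def validate(self) -> None:
        h, w = self.shape
        if h < 3 or w < 3:
            raise ValueError(f"phantom shape must be at least 3x3, got {self.shape}")
        if self.background_mean < 0:
            raise ValueError("background_mean must be non-negative")
        for disc in (*self.cyst_regions, *self.bright_regions):
            r, c = disc.center
            if disc.radius <= 0:
                raise ValueError(f"disc radius must be positive: {disc}")
            if (r - disc.radius < 0 or r + disc.radius > h - 1
                    or c - disc.radius < 0 or c + disc.radius > w - 1):
                raise ValueError(f"disc extends outside the image: {disc}")
        for cyst in self.cyst_regions:
            for bright in self.bright_regions:
                dr = cyst.center[0] - bright.center[0]
                dc = cyst.center[1] - bright.center[1]
                if np.hypot(dr, dc) < cyst.radius + bright.radius:
                    raise ValueError(
                        f"cyst {cyst} and bright region {bright} overlap")


@dataclass(frozen=True)
class SpeckleField:
    """Multiplicative speckle coefficients with their generating parameters."""

    coefficients: np.ndarray = field(repr=False)
    sigma: float
    seed: int


def _distance_map(shape: tuple[int, int], disc: Disc) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rr - disc.center[0], cc - disc.center[1])


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> np.ndarray:
    """Render the clean (noise-free) phantom described by ``spec``.

    The output is deterministic: cyst discs are exactly zero, bright discs
    exactly ``BRIGHT_GAIN * background_mean``, and each region blends into
    the background over a ``TAPER_WIDTH``-pixel ring outside its boundary.
    The ``seed`` argument is accepted for interface symmetry with the noise
    generators; the clean phantom itself contains no randomness.
    """
    spec.validate()
    img = np.full(spec.shape, float(spec.background_mean))
    for disc in spec.cyst_regions:
        d = _distance_map(spec.shape, disc)
        # 0 inside the disc, ramping back to 1 across the taper ring.
        img *= np.clip((d - disc.radius) / TAPER_WIDTH, 0.0, 1.0)
    for disc in spec.bright_regions:
        d = _distance_map(spec.shape, disc)
        gain = np.clip((disc.radius + TAPER_WIDTH - d) / TAPER_WIDTH, 0.0, 1.0)
        img += (BRIGHT_GAIN - 1.0) * spec.background_mean * gain
    return img


def rayleigh_speckle(shape: tuple[int, int], seed: int) -> SpeckleField:
    """Unit-mean Rayleigh amplitude field (fully developed speckle)."""
    if len(shape) != 2 or min(shape) < 1:
        raise ValueError(f"invalid shape {shape}")
    rng = np.random.default_rng(seed)
    raw = rng.rayleigh(scale=1.0, size=shape)
    coeff = raw / np.sqrt(np.pi / 2.0)  # population mean of Rayleigh(1)
    return SpeckleField(coefficients=coeff, sigma=RAYLEIGH_CV, seed=int(seed))


def apply_speckle(
    clean: np.ndarray,
    sigma: float,
    seed: int,
    additive_sigma: float = 0.0,
) -> np.ndarray:
    """Inject multiplicative speckle: ``X = clip(Y * S + A, 0, 255)``.

    ``S = max(1 + sigma * G, 0)`` with ``G`` standard normal, so the field
    has unit mean and standard deviation ``sigma`` (clipping at zero is
    negligible for sigma <= 0.5 and biases the mean upward beyond that).
    ``A`` is zero-mean Gaussian with std ``additive_sigma`` (default: none).
    """
    clean = np.asarray(clean, dtype=float)
    if not 0.0 <= sigma <= 1.5:
        raise ValueError(f"sigma must lie in [0, 1.5], got {sigma}")
    if additive_sigma < 0:
        raise ValueError("additive_sigma must be non-negative")
    if sigma == 0 and additive_sigma == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    s = np.maximum(1.0 + sigma * rng.standard_normal(clean.shape), 0.0)
    x = clean * s
    if additive_sigma > 0:
        x = x + additive_sigma * rng.standard_normal(clean.shape)
    return np.clip(x, 0.0, 255.0)


def default_phantom_spec(shape: tuple[int, int] = (256, 256)) -> PhantomSpec:
    """Reference cyst phantom: three cysts, three bright scatterer spots.

    Region placement is proportional to ``shape`` and keeps the lower-right
    area free of structures so :func:`homogeneous_roi` is pure background.
    The background mean of 25 keeps bright regions (10x) inside the 8-bit
    intensity range.
    """
    h, w = shape
    sy, sx = h / 256.0, w / 256.0
    s = min(sy, sx)
    return PhantomSpec(
        shape=shape,
        cyst_regions=(
            Disc((70 * sy, 60 * sx), 22 * s),
            Disc((70 * sy, 150 * sx), 18 * s),
            Disc((165 * sy, 60 * sx), 20 * s),
        ),
        bright_regions=(
            Disc((60 * sy, 215 * sx), 6 * s),
            Disc((150 * sy, 210 * sx), 5 * s),
            Disc((205 * sy, 60 * sx), 4 * s),
        ),
        background_mean=25.0,
    )


def homogeneous_roi(shape: tuple[int, int] = (256, 256)) -> tuple[int, int, int, int]:
    """Half-open background rectangle ``(r0, c0, r1, c1)`` of the default phantom."""
    h, w = shape
    return (int(184 * h / 256), int(120 * w / 256), int(252 * h / 256), int(248 * w / 256))
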