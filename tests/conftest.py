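import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from cmi3dsvd import apply_speckle, default_phantom_spec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom64():
    """Small clean phantom for fast pipeline tests."""
    return generate_phantom(default_phantom_spec((64, 64)))


@pytest.fixture(scope="session")
def phantom256():
    return generate_phantom(default_phantom_spec((256, 256)))


@pytest.fixture
def textured32(rng):
    """Smoothly varying 32x32 fixture with structure (for metric tests)."""
    x, y = np.meshgrid(np.linspace(0, 4 * np.pi, 32), np.linspace(0, 4 * np.pi, 32))
    img = 120 + 80 * np.sin(x) * np.cos(y / 2) + 10 * rng.standard_normal((32, 32))
    return np.clip(img, 0, 255)


@pytest.fixture
def noisy64(phantom64):
    return apply_speckle(phantom64, 0.2, seed=7)
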