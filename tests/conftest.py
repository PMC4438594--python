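import numpy as np
import pytest

from trabstiff.image_io import BinaryROI
from trabstiff import phantoms

VOX = 0.018  # mm, 18 um scans


@pytest.fixture(scope="session")
def voxel_size():
    return VOX


@pytest.fixture(scope="session")
def ball_roi():
    return BinaryROI(phantoms.ball(8), VOX)


@pytest.fixture(scope="session")
def torus_roi():
    """Torus scaled so TV = 8 mm^3 exactly (Conn.Dn = 1/8 per mm^3)."""
    m = phantoms.torus(8, 3)
    vs = (8.0 / m.size) ** (1.0 / 3.0)
    return BinaryROI(m, vs)


@pytest.fixture(scope="session")
def trabecular_phantom():
    return phantoms.gaussian_trabecular(dims=(48, 40, 40), seed=7)


def random_mask(shape, fill, seed):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < fill
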