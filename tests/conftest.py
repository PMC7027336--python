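import numpy as np
import pytest

from tracerspread import PhantomSpec, brain_mask
from tracerspread.segmentation import BinaryVolume


@pytest.fixture(scope="session")
def small_spec():
    """Small diffusive phantom used by several module tests."""
    return PhantomSpec(shape=(10, 48, 64), seed=42)


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return brain_mask(small_spec)


def random_binary_volume(rng, shape=(8, 8, 4), p=0.1, spacing=None):
    """Random positive set with random anisotropic spacing (test helper)."""
    while True:
        pos = rng.random(shape) < p
        if pos.any() and not pos.all():
            break
    if spacing is None:
        spacing = tuple(rng.uniform(0.5, 5.0, 3))
    return BinaryVolume(positive=pos, mask=np.ones(shape, dtype=bool),
                        spacing_um=spacing, threshold=0.0, method="manual")
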