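import numpy as np
import pytest

from cbctseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default-config phantom shared across tests."""
    return generate_phantom(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def small_phantom():
    """Smaller phantom for tests that resample or iterate."""
    config = PhantomConfig(dims=(48, 64, 64), spacing=(0.8, 0.8, 0.8), seed=7)
    return generate_phantom(config)


def random_blob_mask(rng, shape, max_voxels=1000):
    """Random non-empty binary mask with at most ``max_voxels`` voxels."""
    while True:
        mask = rng.random(shape) < rng.uniform(0.05, 0.4)
        n = int(mask.sum())
        if 0 < n <= max_voxels:
            return mask
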