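import numpy as np
import pytest

from histotex.fixtures import SyntheticSpec, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_tile(rng):
    """One 32×32 random RGB tile."""
    return rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny 4-class synthetic dataset (6 tiles/class, 32×32)."""
    spec = SyntheticSpec(n_per_class=(6, 6, 6, 6), tile_size=32, seed=3)
    return generate(spec)
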