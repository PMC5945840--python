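import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def gaussian_pair(rng):
    """Two independent seeded Gaussian series of length 128."""
    return rng.standard_normal(128), rng.standard_normal(128)


@pytest.fixture
def gaussian_triple(rng):
    """Three correlated seeded series of length 128 (shared component)."""
    shared = rng.standard_normal(128)
    return tuple(shared + 0.8 * rng.standard_normal(128) for _ in range(3))
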