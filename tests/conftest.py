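import numpy as np
import pytest

from epicube.operators import Landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_landscape(rng):
    """A generic dense random landscape, N=6."""
    return Landscape(6, rng.normal(size=64))


def make_random_landscape(n_positions: int, seed: int) -> Landscape:
    rng = np.random.default_rng(seed)
    return Landscape(n_positions, rng.normal(size=1 << n_positions))
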