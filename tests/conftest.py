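import numpy as np
import pytest

from pyrpid import TrivariateDistribution, canonical_gate, random_distribution


@pytest.fixture
def xor():
    return canonical_gate("xor")


@pytest.fixture
def and_gate():
    return canonical_gate("and")


@pytest.fixture
def rdn():
    return canonical_gate("rdn")


@pytest.fixture
def copy_b():
    return canonical_gate("copy_b")


@pytest.fixture
def random_dists():
    """A reproducible batch of modest random distributions of mixed shape."""
    rng = np.random.default_rng(20240901)
    out = []
    for _ in range(30):
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 6)), int(rng.integers(2, 5)))
        out.append(random_distribution(shape, seed=rng))
    return out


@pytest.fixture
def y_constant():
    """Degenerate system: the output never varies."""
    pmf = np.zeros((2, 2, 2))
    pmf[0] = 0.25
    return TrivariateDistribution((0, 1), (0, 1), (0, 1), pmf)
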