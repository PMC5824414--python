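import numpy as np
import pytest

from gimda.census import build_catalog
from gimda.synthetic import PlantedWorldParams, generate_planted_world


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world used across scoring/evaluation tests."""
    params = PlantedWorldParams(
        n_diseases=12, n_mirnas=15, assoc_density=0.8, seed=3
    )
    return generate_planted_world(params)


def random_weighted_graph(n: int, rng: np.random.Generator, binary: bool = False):
    """Symmetric zero-diagonal weight matrix on n nodes."""
    if binary:
        a = (rng.random((n, n)) < 0.45).astype(float)
    else:
        a = rng.random((n, n))
    a = np.triu(a, 1)
    return a + a.T
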