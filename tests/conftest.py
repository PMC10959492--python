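import numpy as np
import pytest

from matepref import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_simplex(rng):
    """A strictly interior random distribution over the 32 genotypes."""
    return rng.dirichlet(np.ones(32))


@pytest.fixture
def defaults():
    return ModelParams()


def random_params(rng, weak: bool = True) -> ModelParams:
    """A random parameter draw in the weak-selection regime."""
    scale = 1.0 if weak else 5.0
    return ModelParams(
        s1=float(rng.uniform(0, 0.02 * scale)),
        s2=float(rng.uniform(0, 0.02 * scale)),
        rho=float(rng.uniform(0.005, 0.02 * scale)),
        c=float(rng.uniform(0, 0.005 * scale)),
        cri=float(rng.uniform(0, 0.005 * scale)),
        a=float(rng.uniform(0.3, 2.0)),
    )
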