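import numpy as np
import pytest

from brainmass import CohortSpec, StructuralConnectome, generate_sc


@pytest.fixture(scope="session")
def small_sc():
    """10-node connected synthetic connectome, weights in [0, 1]."""
    sc, _ = generate_sc(CohortSpec(n_regions=10, n_modules=2, density=0.5, seed=7))
    return sc


@pytest.fixture(scope="session")
def default_sc():
    """Default 68-region synthetic connectome (shared, read-only)."""
    sc, table = generate_sc(CohortSpec(seed=1))
    return sc, table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_symmetric(rng, n, density=0.6, scale=1.0):
    iu = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    vals = rng.random(len(iu[0])) * scale
    vals[rng.random(len(iu[0])) > density] = 0.0
    w[iu] = vals
    w = w + w.T
    return StructuralConnectome(w)
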