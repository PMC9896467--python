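import numpy as np
import pytest

from sphelm.network import DTINetwork
from sphelm.simulate import SyntheticSpec, generate_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_network():
    """Hand-built 3-drug x 3-target network with asymmetric-free similarities."""
    drug_sim = np.array(
        [
            [1.0, 0.6, 0.1],
            [0.6, 1.0, 0.2],
            [0.1, 0.2, 1.0],
        ]
    )
    target_sim = np.array(
        [
            [1.0, 0.5, 0.3],
            [0.5, 1.0, 0.4],
            [0.3, 0.4, 1.0],
        ]
    )
    interactions = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 0],
        ]
    )
    return DTINetwork(["d1", "d2", "d3"], ["t1", "t2", "t3"], drug_sim, target_sim, interactions)


@pytest.fixture(scope="session")
def synthetic_network():
    """Default noise-free planted-cluster benchmark network (40 x 40)."""
    return generate_network(SyntheticSpec(seed=0))


def random_network(rng, n=10, m=10, density=0.25):
    """A valid random network for oracle comparisons."""
    def sim(size):
        S = rng.uniform(0.0, 1.0, size=(size, size))
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        return S

    Y = (rng.random((n, m)) < density).astype(np.int8)
    drug_ids = [f"d{i}" for i in range(n)]
    target_ids = [f"t{j}" for j in range(m)]
    return DTINetwork(drug_ids, target_ids, sim(n), sim(m), Y)
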