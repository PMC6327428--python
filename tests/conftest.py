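import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_net():
    """The 2x2 network from the edge list L1-P1, L1-P2, L2-P2."""
    from acolink.network import InteractionNetwork

    return InteractionNetwork(["L1", "L2"], ["P1", "P2"], [[1, 1], [0, 1]])


@pytest.fixture
def random_net(rng):
    """A 30x20 network with 200 random unique positive pairs."""
    from acolink.network import InteractionNetwork

    adj = np.zeros((30, 20), dtype=int)
    flat = rng.choice(600, size=200, replace=False)
    adj.flat[flat] = 1
    return InteractionNetwork(
        [f"L{i}" for i in range(30)], [f"P{j}" for j in range(20)], adj
    )


@pytest.fixture
def small_block_net():
    """Small planted-block network shared by the CV tests."""
    from acolink.synthetic import BlockNetworkSpec, generate_block_network

    net, labels = generate_block_network(
        BlockNetworkSpec(n_lncrna=40, n_protein=20, n_blocks=4, seed=0)
    )
    return net, labels


def random_row_stochastic(n, rng, zero_diag=True):
    """Random nonnegative row-stochastic matrix with zero diagonal."""
    W = rng.random((n, n))
    if zero_diag:
        np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)
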