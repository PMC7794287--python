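import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynfc as d

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def roi_table():
    return d.make_fixture_roi_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, n, density=0.6):
    """Random symmetric non-negative weighted graph with at least one edge."""
    while True:
        W = rng.uniform(0.0, 1.0, size=(n, n))
        W *= rng.random((n, n)) < density
        W = np.triu(W, k=1)
        W = W + W.T
        if W.sum() > 0:
            return d.Graph(labels=[f"n{i:02d}" for i in range(n)], W=W)


def two_clique_graph(k=4, bridge=0.5):
    """Two k-cliques of unit-weight edges joined by one weak edge."""
    n = 2 * k
    W = np.zeros((n, n))
    W[:k, :k] = 1.0
    W[k:, k:] = 1.0
    np.fill_diagonal(W, 0.0)
    W[k - 1, k] = W[k, k - 1] = bridge
    return d.Graph(labels=[f"n{i:02d}" for i in range(n)], W=W)


@pytest.fixture(scope="session")
def planted_two_block():
    """A 252 s, 32-ROI run with a constant planted 2-community partition."""
    cfg = d.SimConfig(n_rois=32, tr_s=2.0, duration_s=252.0, noise_sd=1.0, seed=7)
    part = d.block_partition(32, 2)
    sch = d.constant_schedule(cfg, part, within_r=0.8, between_r=0.0)
    return d.simulate_roi_bold(cfg, sch), part
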