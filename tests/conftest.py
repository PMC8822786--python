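import numpy as np
import pytest

from scstab import SimPoolSpec, log_normalise, simulate_pool


@pytest.fixture(scope="session")
def three_type_pool():
    """Well-separated 3-type simulation used across estimator tests."""
    spec = SimPoolSpec(n_types=3, cells_per_type=[100, 100, 100], n_genes=500,
                       n_marker_genes_per_type=25, separation=4.0, dispersion=0.2,
                       seed=1)
    return simulate_pool(spec)


@pytest.fixture(scope="session")
def three_type_norm(three_type_pool):
    return log_normalise(three_type_pool)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_partition(rng, n, max_clusters):
    """A uniformly random label vector (clusters may be empty)."""
    return rng.integers(0, max_clusters, size=n)
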