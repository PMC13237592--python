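import pytest

from sublyme import SimulationParams, simulate_embedding_dataset


@pytest.fixture(scope="session")
def small_synth():
    """A small but trainable clustered two-class draw (360 points)."""
    params = SimulationParams(
        dimensionality=16,
        clusters_per_class=12,
        members_per_cluster=15,
        seed=7,
    )
    return simulate_embedding_dataset(params)


@pytest.fixture(scope="session")
def default_synth():
    """The full default separable draw (2000 points, 80 clusters)."""
    return simulate_embedding_dataset(SimulationParams(seed=42))
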