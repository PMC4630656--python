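import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from gradenet.synth import SimulationConfig, simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but complete study: 60 TFs, 3 grades, 2 datasets."""
    return SimulationConfig(n_tfs=60, prior_density=0.3, grades=("II", "III", "IV"),
                            n_datasets=2, samples_per_grade_per_dataset=60,
                            planted_edges_per_grade=8, planted_ffls_per_grade=3,
                            planted_correlation=0.8, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_network(rng, n_nodes, p, prefix="n"):
    """ER digraph helper used across test modules."""
    from gradenet.network import DirectedNetwork

    mask = rng.random((n_nodes, n_nodes)) < p
    np.fill_diagonal(mask, False)
    edges = {(f"{prefix}{i}", f"{prefix}{j}")
             for i, j in zip(*np.nonzero(mask))}
    net = DirectedNetwork.from_edges(edges)
    net.nodes |= {f"{prefix}{i}" for i in range(n_nodes)}
    return net
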