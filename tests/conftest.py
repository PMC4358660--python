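import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

import moanet
import moanet.diffusion as diffusion
import moanet.network as network

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def build_weighted(fixture: dict) -> nx.Graph:
    """Expression-filtered, co-regulation-weighted network of a fixture."""
    filtered = network.filter_expressed(fixture["network"], fixture["expression"])
    fc = network.fold_changes(fixture["expression"])
    return network.weight_edges(filtered, fc)


@pytest.fixture(scope="session")
def fixture_small():
    """Small complete synthetic input set (200 nodes, 20-gene module)."""
    return moanet.make_fixture(
        rng_seed=11, n_nodes=200, module_size=20, n_terms=50, n_targets=5
    )


@pytest.fixture(scope="session")
def wnet_small(fixture_small):
    return build_weighted(fixture_small)


@pytest.fixture(scope="session")
def seeds_small(fixture_small):
    return diffusion.seeds_from_counts(fixture_small["targets"])


@pytest.fixture(scope="session")
def diffusion_small(wnet_small, seeds_small):
    return diffusion.rwr(wnet_small, seeds_small)
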