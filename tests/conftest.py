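import pytest

from cicnet import GeneNetwork, synthesize_truth


@pytest.fixture
def chain_net() -> GeneNetwork:
    """A -> B -> C -> D."""
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def star_net() -> GeneNetwork:
    """Hub R with ten leaf children m1..m10."""
    return GeneNetwork.from_edges([("R", f"m{i}") for i in range(1, 11)])


@pytest.fixture(scope="session")
def planted_truth():
    """One 500-gene hub-rooted synthetic truth shared across tests."""
    return synthesize_truth(n_genes=500, n_hubs=10, rng_seed=2024)
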