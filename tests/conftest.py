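import pytest

from cdepp.simulate import SimConfig, simulate_dataset, simulate_species_tree
from cdepp.trees import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar():
    return parse_newick("(((A:1,B:1):1,C:1):1,D:1);")


@pytest.fixture
def random_tree():
    def make(n, seed=0, death=0.0):
        return simulate_species_tree(n, 1.0, death, seed=seed)

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic simulated dataset reused by the slower tests."""
    return simulate_dataset(SimConfig(n_species=48, seq_length=200, seed=2))


@pytest.fixture(scope="session")
def tiny_placer(small_dataset):
    """A small trained ensemble shared across pipeline tests."""
    from cdepp.pipeline import ClusteredPlacer

    ds = small_dataset
    placer = ClusteredPlacer(m=16, m_prime=4, embedding_dim=16, channels=16,
                             epochs=80, classifier_epochs=150, lr=1e-3, seed=1)
    placer.fit(ds.backbone, ds.backbone_seqs(0))
    return placer
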