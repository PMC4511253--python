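import numpy as np
import pytest

from funlink.netcore import EvidenceNetwork, IntegratedNetwork
from funlink.prioritize import ReferenceGeneSet


def random_evidence_network(rng: np.random.Generator, n_genes: int = 12, p: float = 0.3,
                            source_id: str = "rand") -> EvidenceNetwork:
    genes = [f"g{i}" for i in range(n_genes)]
    net = EvidenceNetwork(source_id=source_id)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                net.add_edge(genes[i], genes[j], float(rng.uniform(-5, 20)))
    return net


def random_integrated_network(rng: np.random.Generator, n_genes: int = 20, p: float = 0.25
                              ) -> IntegratedNetwork:
    genes = [f"g{i}" for i in range(n_genes)]
    net = IntegratedNetwork()
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                net.add_edge(genes[i], genes[j], float(rng.uniform(0, 1)), {"src"})
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_integrated():
    """4-gene path/star mix with known confidences."""
    net = IntegratedNetwork()
    net.add_edge("i", "r1", 0.8, {"a"})
    net.add_edge("i", "r2", 0.2, {"a", "b"})
    net.add_edge("r1", "r2", 0.5, {"b"})
    net.add_edge("i", "x", 0.9, {"a"})
    return net


@pytest.fixture
def growth_refs():
    return ReferenceGeneSet(trait_label="growth", genes=frozenset({"r1", "r2"}))
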