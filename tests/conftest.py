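import numpy as np
import pytest

from phytonet import KGEdge, KnowledgeGraph, SyntheticSpec
from phytonet.curated import curated_mini_network


@pytest.fixture
def mini_network() -> KnowledgeGraph:
    """Curated compound-target layer (the in-study worked example)."""
    return curated_mini_network()


@pytest.fixture
def spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


def random_typed_graph(rng: np.random.Generator, n_nodes: int = 20, p: float = 0.15):
    """Small random typed graph for property checks."""
    graph = KnowledgeGraph()
    types = ["compound", "protein", "metabolite", "phenotype", "marker"]
    ids = []
    for i in range(n_nodes):
        node = graph.ensure_node(f"n{i:02d}", types[i % len(types)])
        ids.append(node.id)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                graph.add_edge(KGEdge(ids[i], ids[j], "interacts"))
    return graph, ids
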