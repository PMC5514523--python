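"""Shared fixtures: tiny hand-built graphs, ontologies and annotation sets."""

import networkx as nx
import numpy as np
import pytest

from signprop import (
    AssociationSet,
    GeneNetwork,
    Ontology,
    SimulationConfig,
    generate_network,
    plant_annotations,
)
from signprop.io import DiseaseMeta


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star() -> GeneNetwork:
    return GeneNetwork.from_edges([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def path3() -> GeneNetwork:
    return GeneNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def chain_ontology() -> Ontology:
    """A <- B <- C (A is root)."""
    return Ontology({"A": set(), "B": {"A"}, "C": {"B"}})


@pytest.fixture
def small_assoc() -> AssociationSet:
    return AssociationSet(
        disease_genes={"D1": {"G1", "G2"}, "D2": {"G2", "G3"}, "D3": set()},
        disease_signs={
            "D1": {"C": "hallmark"},
            "D2": {"C": "occasional"},
            "D3": {"B": "typical"},
        },
        disease_meta={
            "D1": DiseaseMeta(inheritance="AD", onset=frozenset({"neonatal", "infantile"}),
                              progression="slow"),
            "D2": DiseaseMeta(inheritance="AR", onset=frozenset({"adult"}),
                              progression="nonprogressive"),
        },
        gene_functions={"G1": {"FN:1"}, "G2": {"FN:1", "FN:2"}},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 400-node planted dataset used by several integration tests."""
    cfg = SimulationConfig(
        n_nodes=400, n_diseases=50, n_signs=10, diseases_per_sign=(4, 8),
        module_density=0.25, mono_weight=0.8, rng_seed=11,
    )
    net = generate_network(cfg)
    return plant_annotations(net, cfg)


def random_connected_graph(rng: np.random.Generator, n_max: int = 50) -> GeneNetwork:
    """Random connected graph on 4..n_max nodes (spanning tree + extra edges)."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(0, 2**31)))
    extra = int(rng.integers(0, 2 * n))
    nodes = list(g.nodes)
    for _ in range(extra):
        a, b = rng.choice(len(nodes), size=2, replace=False)
        g.add_edge(nodes[a], nodes[b])
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return GeneNetwork(g)
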