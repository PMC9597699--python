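"""Shared fixtures: tiny hand-built networks and a reduced synthetic scenario."""

import networkx as nx
import pytest

from endosig.netio import GeneNetwork, GeneSet, build_degree_index
from endosig.synthdata import ScenarioConfig, generate_scenario


def make_net(edges, name="net", nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=e[2])
        else:
            g.add_edge(*e)
    return GeneNetwork(g, name=name)


@pytest.fixture
def path_net():
    return make_net([("a", "b"), ("b", "c")])


@pytest.fixture
def clique4():
    g = nx.complete_graph(["a", "b", "c", "d"])
    return GeneNetwork(g, name="clique4")


@pytest.fixture
def star5():
    return make_net([("h", f"l{i}") for i in range(5)], name="star5")


@pytest.fixture
def two_cliques():
    """Two disjoint 10-cliques; a perfectly separable expansion fixture."""
    g = nx.Graph()
    p_nodes = [f"p{i}" for i in range(10)]
    n_nodes = [f"n{i}" for i in range(10)]
    g.add_edges_from(nx.complete_graph(p_nodes).edges)
    g.add_edges_from(nx.complete_graph(n_nodes).edges)
    return GeneNetwork(g, name="two_cliques"), p_nodes, n_nodes


def small_scenario_config(rng_seed=0):
    """A reduced scenario keeping the default's statistical shape:
    ~10% of genes in CI blocks, same seed fractions and drug placements."""
    return ScenarioConfig(
        n_genes=800,
        n_blocks=16,
        p_within=0.25,
        p_between=0.008,
        ci_blocks=(0, 1),
        n_ci_genes=50,
        disease_specs=[(f"disease_{i}", 40, 0.6, 0.4) for i in range(3)],
        trait_specs=[(f"trait_{i}", 40) for i in range(3)],
        drug_specs=(
            [(f"cidrug_{i}", 5, "ci_module") for i in range(3)]
            + [(f"rdrug_{i}", 5, "random") for i in range(6)]
        ),
        n_extra_annotations=10,
        extra_annotation_size=40,
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(small_scenario_config(rng_seed=3))


@pytest.fixture(scope="session")
def small_index(small_scenario):
    return build_degree_index(small_scenario.network)


@pytest.fixture
def geneset():
    def _make(id, genes):
        return GeneSet(id, genes=frozenset(genes))

    return _make
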