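import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from clinrank import Query, build_stats, figure1_fixture
from clinrank.graph import DataGraph, Edge, Node


@pytest.fixture(scope="session")
def fixture_graph():
    return figure1_fixture()


@pytest.fixture(scope="session")
def fixture_stats(fixture_graph):
    return build_stats(fixture_graph)


@pytest.fixture
def pe_query():
    return Query.from_string("pericardial effusion")


def random_graph(seed: int, n: int | None = None, p: float = 0.15) -> DataGraph:
    """A random labelled digraph whose nodes all contain the term 'record'
    (so a query on it has base set S = V) and some contain 'alpha'."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(3, 51))
    nodes = []
    for i in range(n):
        text = "record"
        if rng.random() < 0.4:
            text += " alpha"
        nodes.append(Node(f"n{i:03d}", "Entity", (("text", text),)))
    graph = DataGraph(nodes)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                graph.add_edge(Edge(f"n{i:03d}", f"n{j:03d}", "link"))
    return graph
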