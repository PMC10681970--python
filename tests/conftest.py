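import itertools

import pytest

from mesotypes import Graph, Partition


@pytest.fixture
def write_file(tmp_path):
    """Write text content to a temp file and return its path as str."""

    def _write(name: str, content: str) -> str:
        p = tmp_path / name
        p.write_text(content, encoding="utf-8")
        return str(p)

    return _write


@pytest.fixture
def two_cliques_undirected():
    """Two disconnected 3-cliques; the unique modularity-optimal 2-split."""
    g = Graph(directed=False)
    for a, b in itertools.combinations(["a", "b", "c"], 2):
        g.add_edge(a, b)
    for a, b in itertools.combinations(["x", "y", "z"], 2):
        g.add_edge(a, b)
    return g


def make_directed_graph(edges, nodes=()):
    g = Graph(directed=True)
    for n in nodes:
        g.add_node(n)
    for e in edges:
        g.add_edge(*e)
    return g


@pytest.fixture
def spec_example_graph():
    """Directed: blocks r={1,2}, s={3,4}, edges 1→2, 2→1, 1→3, 3→4."""
    g = make_directed_graph([("1", "2"), ("2", "1"), ("1", "3"), ("3", "4")])
    p = Partition({"1": "r", "2": "r", "3": "s", "4": "s"})
    return g, p
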