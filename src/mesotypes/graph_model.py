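"""Multigraph and partition data model plus file readers/writers.

The graph is a node set together with a multiset of edges: ordered pairs for
directed graphs, unordered pairs (stored once under a canonical endpoint
order) for undirected graphs.  Edge multiplicities are positive integers, so
the adjacency matrix A_ij takes values in the natural numbers; non-integer
edge weights are rejected.  Self-loops are accepted on input and flagged, but
excluded from all density computations downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping

import networkx as nx

from .errors import ConflictError, CoverageError, GraphParseError, UsageError

logger = logging.getLogger(__name__)

Node = Hashable


def _canonical_pair(u: Node, v: Node) -> tuple[Node, Node]:
    """Canonical endpoint order for an undirected edge."""
    try:
        return (u, v) if u <= v else (v, u)  # type: ignore[operator]
    except TypeError:
        return (u, v) if str(u) <= str(v) else (v, u)


@dataclass
class Graph:
    """A directed or undirected multigraph with integer edge multiplicities.

    Parameters
    ----------
    directed
        Whether edges are ordered pairs.

    Attributes
    ----------
    nodes : set
        Node identifiers (opaque hashables; loaders produce strings).
    """

    directed: bool
    nodes: set = field(default_factory=set)
    _edges: dict = field(default_factory=dict)

    def add_node(self, u: Node) -> None:
        self.nodes.add(u)

    def add_edge(self, u: Node, v: Node, multiplicity: int = 1) -> None:
        """Accumulate ``multiplicity`` onto the (u, v) edge."""
        if not isinstance(multiplicity, int) or isinstance(multiplicity, bool):
            raise UsageError(f"edge multiplicity must be an integer, got {multiplicity!r}")
        if multiplicity < 1:
            raise UsageError(f"edge multiplicity must be >= 1, got {multiplicity}")
        self.nodes.add(u)
        self.nodes.add(v)
        key = (u, v) if self.directed else _canonical_pair(u, v)
        self._edges[key] = self._edges.get(key, 0) + multiplicity

    def multiplicity(self, u: Node, v: Node) -> int:
        """A_uv: total multiplicity from u to v (or between u and v)."""
        key = (u, v) if self.directed else _canonical_pair(u, v)
        return self._edges.get(key, 0)

    def edges(self) -> Iterator[tuple[Node, Node, int]]:
        """Iterate (u, v, multiplicity) over distinct stored edges."""
        for (u, v), m in self._edges.items():
            yield u, v, m

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Total edge multiplicity (self-loops included)."""
        return sum(self._edges.values())

    @property
    def self_loop_nodes(self) -> set:
        return {u for (u, v) in self._edges if u == v}

    @property
    def has_self_loops(self) -> bool:
        return any(u == v for (u, v) in self._edges)

    def reversed(self) -> "Graph":
        """The graph with every directed edge (u, v) stored as (v, u)."""
        if not self.directed:
            raise UsageError("cannot reverse edges of an undirected graph")
        g = Graph(directed=True, nodes=set(self.nodes))
        g._edges = {(v, u): m for (u, v), m in self._edges.items()}
        return g

    def out_degree(self, u: Node) -> int:
        """Multiplicity-weighted out-degree (undirected: total degree)."""
        if self.directed:
            return sum(m for (a, _b), m in self._edges.items() if a == u)
        return sum(m for (a, b), m in self._edges.items() if u in (a, b))

    def in_degree(self, u: Node) -> int:
        if self.directed:
            return sum(m for (_a, b), m in self._edges.items() if b == u)
        return self.out_degree(u)

    def degrees(self) -> tuple[dict, dict]:
        """(in_degree, out_degree) maps for all nodes in one pass."""
        din = {u: 0 for u in self.nodes}
        dout = {u: 0 for u in self.nodes}
        for (u, v), m in self._edges.items():
            if self.directed:
                dout[u] += m
                din[v] += m
            else:
                dout[u] += m
                dout[v] += m
        if not self.directed:
            din = dout
        return din, dout


@dataclass(frozen=True)
class Partition:
    """Assignment of every graph node to exactly one of B disjoint blocks."""

    assignment: Mapping[Node, Hashable]

    @property
    def B(self) -> int:
        return len(self.sizes)

    @property
    def sizes(self) -> dict:
        sizes: dict = {}
        for b in self.assignment.values():
            sizes[b] = sizes.get(b, 0) + 1
        return sizes

    @property
    def block_labels(self) -> list:
        return sorted(self.sizes, key=str)

    def members(self, block: Hashable) -> list:
        return [u for u, b in self.assignment.items() if b == block]

    def validate_against(self, graph: Graph) -> None:
        """Raise CoverageError unless blocks exactly cover the node set."""
        assigned = set(self.assignment)
        missing = graph.nodes - assigned
        extra = assigned - graph.nodes
        if missing:
            raise CoverageError(
                f"partition does not cover {len(missing)} graph node(s), "
                f"e.g. {sorted(map(str, missing))[:5]}"
            )
        if extra:
            raise CoverageError(
                f"partition names {len(extra)} unknown node(s), "
                f"e.g. {sorted(map(str, extra))[:5]}"
            )


def _parse_edgelist(path: str, directed: bool) -> Graph:
    g = Graph(directed=directed)
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 2:
                u, v = fields
                mult = 1
            elif len(fields) == 3:
                u, v, ms = fields
                try:
                    mult = int(ms)
                except ValueError:
                    raise GraphParseError(
                        f"{path}:{lineno}: multiplicity column is not an "
                        f"integer: {ms!r}"
                    ) from None
                if mult < 1:
                    raise GraphParseError(
                        f"{path}:{lineno}: multiplicity must be >= 1, got {mult}"
                    )
            else:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 or 3 whitespace-separated "
                    f"columns, found {len(fields)}"
                )
            g.add_edge(u, v, mult)
    return g


def _from_networkx(nxg, directed: bool) -> Graph:
    g = Graph(directed=directed)
    for n in nxg.nodes:
        g.add_node(str(n))
    for u, v, data in nxg.edges(data=True):
        w = data.get("weight", 1)
        if isinstance(w, float):
            if not w.is_integer():
                raise GraphParseError(
                    f"non-integer edge weight {w!r} on edge ({u}, {v}); "
                    "only integer multiplicities are supported"
                )
            w = int(w)
        g.add_edge(str(u), str(v), int(w))
    return g


def load_graph(
    path: str,
    format: str = "edgelist",
    directed: bool = True,
    reverse_edges: bool = False,
) -> Graph:
    """Load a multigraph from an edge list, GML, or GraphML file.

    Edge-list dialect: whitespace- or tab-separated ``source target
    [multiplicity]``; lines starting with ``#`` are ignored; repeated
    identical lines accumulate multiplicity.  ``reverse_edges`` stores every
    directed edge (i, j) as (j, i) — use it when the file's arrow convention
    is opposite to the flow of influence/information you want A_ij to encode.
    """
    if reverse_edges and not directed:
        raise UsageError("reverse_edges is meaningless for an undirected graph")
    if format == "edgelist":
        g = _parse_edgelist(path, directed)
    elif format == "gml":
        nxg = nx.read_gml(path, label="id")
        g = _from_networkx(nxg, directed)
    elif format == "graphml":
        nxg = nx.read_graphml(path)
        g = _from_networkx(nxg, directed)
    else:
        raise UsageError(f"unknown graph format: {format!r}")
    if g.has_self_loops:
        logger.warning(
            "graph contains self-loops on %d node(s); they are excluded from "
            "density computations",
            len(g.self_loop_nodes),
        )
    if reverse_edges:
        g = g.reversed()
    return g


def write_graph(graph: Graph, path: str) -> None:
    """Write the graph as a three-column edge list TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v, m in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\t{m}\n")
        for u in sorted(graph.nodes, key=str):
            if graph.in_degree(u) == 0 and graph.out_degree(u) == 0:
                fh.write(f"# isolated\t{u}\n")


def load_partition(path: str, graph: Graph) -> Partition:
    """Load a two-column (node TAB block) partition covering the graph."""
    assignment: dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 columns (node, block), "
                    f"found {len(fields)}"
                )
            node, block = fields
            if node in assignment:
                raise ConflictError(f"{path}:{lineno}: node {node!r} assigned twice")
            assignment[node] = block
    part = Partition(assignment)
    part.validate_against(graph)
    return part


def write_partition(partition: Partition, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for node in sorted(partition.assignment, key=str):
            fh.write(f"{node}\t{partition.assignment[node]}\n")


def load_attributes(path: str, graph: Graph) -> dict:
    """Load a node-attribute TSV (node, attr1, attr2, ...) with a header row.

    Returns {node: {attr_name: value}}.  Every named node must exist in the
    graph; nodes absent from the table simply carry no attributes.
    """
    table: dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GraphParseError(f"{path}: empty attribute table")
        cols = header.split("\t") if "\t" in header else header.split()
        if len(cols) < 2:
            raise GraphParseError(f"{path}: attribute table needs >= 2 columns")
        attr_names = cols[1:]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != len(cols):
                raise GraphParseError(
                    f"{path}:{lineno}: expected {len(cols)} columns, "
                    f"found {len(fields)}"
                )
            node = fields[0]
            if node not in graph.nodes:
                raise CoverageError(f"{path}:{lineno}: unknown node {node!r}")
            table[node] = dict(zip(attr_names, fields[1:]))
    return table
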