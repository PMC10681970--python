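"""Partition providers and the increasing-B sweep.

Community detection itself is out of scope: serious detectors (Louvain,
Infomap, spectral, degree-corrected SBM, DNGR) live outside the package and
plug in through :class:`DetectorAdapter`, a small contract — given a graph,
an optional requested block count B, and a seed, return a Partition of the
graph.  Built-ins cover the hermetic cases: the planted-truth oracle (with a
deterministic merge hierarchy for B below the planted count), a fixed
partition file, and a seeded greedy directed-modularity detector kept for
convenience on small graphs.

``sweep_B`` is the case-study procedure: grow B from 2 upward and stop at
the first B whose pair classifications contain anything beyond assortative —
the simplest setting in which nonassortative structure appears.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classification import RelationshipType, classify_all_pairs
from .density import compute_density
from .errors import UsageError
from .graph_model import Graph, Partition, load_partition, write_graph
from .profiling import TypeProfile, profile_from_classifications

logger = logging.getLogger(__name__)


class DetectorAdapter:
    """Contract: ``detect(graph, B, seed) -> Partition`` on that graph."""

    name: str = "abstract"
    accepts_B: bool = False

    def detect(self, graph: Graph, B: int | None = None, seed: int = 0) -> Partition:
        raise NotImplementedError


class OracleDetector(DetectorAdapter):
    """Returns the planted truth; merges trailing blocks when B is smaller.

    For a requested B below the planted block count, the first B−1 planted
    blocks (label order) are kept and the rest merged into one — a
    deterministic stand-in for the coarser partitions a real detector would
    report before the structure of interest resolves.
    """

    accepts_B = True

    def __init__(self, truth: Partition, name: str = "oracle"):
        self.truth = truth
        self.name = name

    def detect(self, graph: Graph, B: int | None = None, seed: int = 0) -> Partition:
        truth_B = self.truth.B
        if B is None or B >= truth_B:
            return self.truth
        if B < 1:
            raise UsageError(f"requested B must be >= 1, got {B}")
        labels = self.truth.block_labels
        keep = set(labels[: B - 1])
        merged = str(labels[B - 1]) + "+"
        assignment = {
            u: (b if b in keep else merged) for u, b in self.truth.assignment.items()
        }
        return Partition(assignment)


class FileDetector(DetectorAdapter):
    """Serves a fixed partition from a two-column TSV file."""

    accepts_B = False

    def __init__(self, path: str, name: str | None = None):
        self.path = path
        self.name = name or f"file:{path}"

    def detect(self, graph: Graph, B: int | None = None, seed: int = 0) -> Partition:
        return load_partition(self.path, graph)


class CommandDetector(DetectorAdapter):
    """Runs an external detector subprocess.

    The command is invoked as ``argv + [edgelist_path, str(B), str(seed),
    out_path]`` and must write a two-column partition TSV to ``out_path``.
    """

    accepts_B = True

    def __init__(self, argv: list[str], name: str | None = None):
        self.argv = list(argv)
        self.name = name or Path(argv[0]).name

    def detect(self, graph: Graph, B: int | None = None, seed: int = 0) -> Partition:
        with tempfile.TemporaryDirectory() as tmp:
            gpath = str(Path(tmp) / "graph.tsv")
            ppath = str(Path(tmp) / "partition.tsv")
            write_graph(graph, gpath)
            cmd = self.argv + [gpath, str(B if B is not None else 0), str(seed), ppath]
            res = subprocess.run(cmd, capture_output=True, text=True)
            if res.returncode != 0:
                raise UsageError(
                    f"detector {self.name!r} failed (exit {res.returncode}): "
                    f"{res.stderr.strip()[:500]}"
                )
            return load_partition(ppath, graph)


def modularity(graph: Graph, assignment: dict) -> float:
    """Modularity of a partition: within/m − Σ_b k_b^out k_b^in / M².

    Directed (Newman–Leicht): M = m.  Undirected: degrees count each edge at
    both endpoints, so M = 2m and the penalty is the classic (d_b / 2m)².
    """
    m = graph.n_edges
    if m == 0:
        return 0.0
    din, dout = graph.degrees()
    within = sum(w for u, v, w in graph.edges() if assignment[u] == assignment[v])
    blocks: dict = {}
    for u, b in assignment.items():
        so, si = blocks.get(b, (0, 0))
        blocks[b] = (so + dout[u], si + din[u])
    M = m if graph.directed else 2 * m
    return within / m - sum(so * si for so, si in blocks.values()) / (M * M)


class GreedyModularityDetector(DetectorAdapter):
    """Seeded random init into B blocks + greedy single-node moves.

    Maximizes directed modularity (Newman–Leicht form); for undirected
    graphs each edge contributes to both endpoint degrees, which reduces to
    classic modularity up to constant factors and leaves the argmax
    unchanged.  Deterministic given the seed.
    """

    name = "greedy-modularity"
    accepts_B = True

    def detect(self, graph: Graph, B: int | None = None, seed: int = 0) -> Partition:
        if B is None:
            raise UsageError("greedy detector requires a requested B")
        n = graph.n_nodes
        if B < 1:
            raise UsageError(f"B must be >= 1, got {B}")
        if B > n:
            raise UsageError(f"B={B} exceeds the node count {n}")
        rng = np.random.default_rng(seed)
        nodes = sorted(graph.nodes, key=str)
        # every block non-empty, remainder random
        init = list(range(B)) + rng.integers(0, B, size=n - B).tolist()
        rng.shuffle(nodes)
        assignment = {u: int(b) for u, b in zip(nodes, init)}
        m = graph.n_edges
        if m:
            din, dout = graph.degrees()
            # undirected adjacency/degrees double-count each edge; 2m keeps
            # the gain proportional to the true modularity delta
            self._greedy_pass(graph, assignment, B, din, dout, m if graph.directed else 2 * m)
        return Partition({u: str(b) for u, b in assignment.items()})

    @staticmethod
    def _greedy_pass(graph, assignment, B, din, dout, m):
        # adjacency lists for delta evaluation
        out_adj: dict = {u: [] for u in assignment}
        in_adj: dict = {u: [] for u in assignment}
        for u, v, w in graph.edges():
            out_adj[u].append((v, w))
            in_adj[v].append((u, w))
            if not graph.directed and u != v:
                out_adj[v].append((u, w))
                in_adj[u].append((v, w))
        blk_out = {b: 0 for b in range(B)}
        blk_in = {b: 0 for b in range(B)}
        for u, b in assignment.items():
            blk_out[b] += dout[u]
            blk_in[b] += din[u]
        order = sorted(assignment, key=str)
        improved = True
        sweeps = 0
        while improved and sweeps < 100:
            improved = False
            sweeps += 1
            for u in order:
                b0 = assignment[u]
                # links from/to u into each block (excluding self-loops)
                link: dict = {}
                for v, w in out_adj[u]:
                    if v != u:
                        link[assignment[v]] = link.get(assignment[v], 0) + w
                for v, w in in_adj[u]:
                    if v != u:
                        link[assignment[v]] = link.get(assignment[v], 0) + w
                best_b, best_gain = b0, 0.0
                for b1 in range(B):
                    if b1 == b0:
                        continue
                    d_within = link.get(b1, 0) - link.get(b0, 0)
                    d_expected = (
                        dout[u] * (blk_in[b1] - (blk_in[b0] - din[u]))
                        + din[u] * (blk_out[b1] - (blk_out[b0] - dout[u]))
                    ) / m
                    gain = d_within - d_expected
                    if gain > best_gain + 1e-12:
                        best_b, best_gain = b1, gain
                if best_b != b0:
                    blk_out[b0] -= dout[u]
                    blk_in[b0] -= din[u]
                    blk_out[best_b] += dout[u]
                    blk_in[best_b] += din[u]
                    assignment[u] = best_b
                    improved = True


def builtin_greedy(graph: Graph, B: int, seed: int = 0) -> Partition:
    """Convenience wrapper around :class:`GreedyModularityDetector`."""
    return GreedyModularityDetector().detect(graph, B=B, seed=seed)


@dataclass
class SweepReport:
    """Outcome of the increasing-B sweep."""

    B_min: int
    B_max: int
    detector: str
    profiles: dict  # B -> TypeProfile
    partitions: dict  # B -> Partition
    first_nonassortative_B: int | None
    triggering_pairs: list = field(default_factory=list)  # (pair, type) at that B
    exhausted: bool = False

    def to_dict(self) -> dict:
        return {
            "B_min": self.B_min,
            "B_max": self.B_max,
            "detector": self.detector,
            "first_nonassortative_B": self.first_nonassortative_B,
            "exhausted": self.exhausted,
            "triggering_pairs": [
                {"pair": [str(a) for a in pair], "type": t.value}
                for pair, t in self.triggering_pairs
            ],
            "profiles": {
                str(B): {
                    "fractions": {
                        t.value: float(f) for t, f in prof.fractions.items()
                    },
                    "dominant": getattr(prof.dominant, "value", str(prof.dominant)),
                    "n_pairs": prof.n_pairs,
                }
                for B, prof in self.profiles.items()
            },
        }


def sweep_B(
    graph: Graph,
    detector: DetectorAdapter,
    B_min: int = 2,
    B_max: int = 10,
    seed: int = 0,
) -> SweepReport:
    """Increase B until the first nonassortative, non-degenerate pair.

    For each B from B_min to B_max: obtain a partition from the detector,
    compute ω, classify all pairs.  Stops at the first B whose profile
    contains any pair typed other than assortative or degenerate and reports
    that B with the triggering pairs; otherwise reports exhaustion at B_max.
    """
    if B_min < 2:
        raise UsageError(f"B_min must be >= 2, got {B_min}")
    if B_max < B_min:
        raise UsageError(f"B_max={B_max} below B_min={B_min}")
    if not detector.accepts_B:
        raise UsageError(f"detector {detector.name!r} does not accept a requested B")
    profiles: dict = {}
    partitions: dict = {}
    for B in range(B_min, B_max + 1):
        try:
            part = detector.detect(graph, B=B, seed=seed)
        except Exception as exc:
            raise UsageError(
                f"detector {detector.name!r} failed at B={B}: {exc}"
            ) from exc
        omega = compute_density(graph, part)
        pairs = classify_all_pairs(omega)
        prof = profile_from_classifications(pairs)
        profiles[B] = prof
        partitions[B] = part
        triggers = [
            (p.pair, p.type)
            for p in pairs
            if p.type
            not in (RelationshipType.ASSORTATIVE, RelationshipType.DEGENERATE)
        ]
        if triggers:
            return SweepReport(
                B_min=B_min,
                B_max=B_max,
                detector=detector.name,
                profiles=profiles,
                partitions=partitions,
                first_nonassortative_B=B,
                triggering_pairs=triggers,
            )
    return SweepReport(
        B_min=B_min,
        B_max=B_max,
        detector=detector.name,
        profiles=profiles,
        partitions=partitions,
        first_nonassortative_B=None,
        exhausted=True,
    )
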