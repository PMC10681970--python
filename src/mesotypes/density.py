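"""Edge-density matrix ω of a partitioned multigraph.

ω_rs is the ratio of existing links from block r to block s over the number
of possible such links: N_r·N_s between distinct blocks, N_r(N_r−1) within a
block of a directed graph, and ½N_r(N_r−1) within a block of an undirected
graph.  Self-loops never count: the possible-link denominators exclude i = j,
so their multiplicities are dropped from the numerators too.

Entries are exact rationals (`fractions.Fraction`), never floats: the
downstream classifier treats exact ties as a separate DEGENERATE outcome, and
that decision must not depend on floating-point round-off.  For multigraphs
entries may exceed 1 and are returned unclamped.

Block labels are reordered canonically so that ω_rr ≥ ω_ss for r < s.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import CoverageError, UsageError
from .graph_model import Graph, Partition

logger = logging.getLogger(__name__)


@dataclass
class DensityMatrix:
    """B×B matrix of exact block-pair densities.

    ``entries[i][j]`` is ω for (block_labels[i], block_labels[j]); in the
    directed case the row block is the source of the links.  ``singleton``
    flags blocks of size 1, whose within-block density is 0/0 and stored as 0.
    """

    block_labels: list
    entries: list  # list of list of Fraction
    directed: bool
    sizes: dict
    singleton: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return len(self.block_labels)

    def omega(self, r, s) -> Fraction:
        i = self.block_labels.index(r)
        j = self.block_labels.index(s)
        return self.entries[i][j]

    def is_singleton(self, r) -> bool:
        return bool(self.singleton.get(r, False))

    def as_array(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.entries])

    def to_csv(self, path: str) -> None:
        """Floats at 12 significant digits; labels as first row/column."""
        with open(path, "wt", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["block"] + [str(b) for b in self.block_labels])
            for label, row in zip(self.block_labels, self.entries):
                w.writerow([str(label)] + [f"{float(x):.12g}" for x in row])

    def to_json(self, path: str) -> None:
        """Exact numerator/denominator sidecar with singleton flags."""
        payload = {
            "directed": self.directed,
            "block_labels": [str(b) for b in self.block_labels],
            "sizes": {str(b): self.sizes[b] for b in self.block_labels},
            "singleton": {str(b): self.is_singleton(b) for b in self.block_labels},
            "entries": [
                [{"numerator": x.numerator, "denominator": x.denominator} for x in row]
                for row in self.entries
            ],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def compute_density(graph: Graph, partition: Partition) -> DensityMatrix:
    """Compute the edge-density matrix of ``graph`` under ``partition``.

    Raises CoverageError if the partition does not exactly cover the node
    set.  Singleton blocks get a zero diagonal entry with a flag raised (the
    0/0 case has no principled value) and a logged warning.
    """
    partition.validate_against(graph)
    labels = partition.block_labels
    sizes = partition.sizes
    index = {b: i for i, b in enumerate(labels)}
    B = len(labels)
    assign = partition.assignment

    counts = [[0] * B for _ in range(B)]
    for u, v, m in graph.edges():
        if u == v:
            continue  # self-loops excluded
        i, j = index[assign[u]], index[assign[v]]
        counts[i][j] += m

    if not graph.directed:
        # an undirected cross edge was tallied once under whichever endpoint
        # order the graph stored; fold both orders into the unordered count
        for i in range(B):
            for j in range(i + 1, B):
                tot = counts[i][j] + counts[j][i]
                counts[i][j] = counts[j][i] = tot

    entries = [[Fraction(0)] * B for _ in range(B)]
    singleton = {}
    for r, br in enumerate(labels):
        nr = sizes[br]
        for s, bs in enumerate(labels):
            ns = sizes[bs]
            if r == s:
                if nr == 1:
                    singleton[br] = True
                    entries[r][s] = Fraction(0)
                    logger.warning(
                        "block %r is a singleton; its within-block density "
                        "is undefined and stored as 0 (flagged)",
                        br,
                    )
                else:
                    denom = nr * (nr - 1)
                    if not graph.directed:
                        denom //= 2
                    entries[r][s] = Fraction(counts[r][s], denom)
            else:
                entries[r][s] = Fraction(counts[r][s], nr * ns)
        singleton.setdefault(br, False)

    # canonical ordering: self-density descending, ties by label order
    self_d = [entries[i][i] for i in range(B)]
    order = sorted(range(B), key=lambda i: (-self_d[i], str(labels[i])))
    if any(
        self_d[order[k]] == self_d[order[k + 1]] for k in range(B - 1)
    ):
        logger.info("tied self-densities; canonical order broken by block label")
    new_labels = [labels[i] for i in order]
    new_entries = [[entries[i][j] for j in order] for i in order]
    return DensityMatrix(
        block_labels=new_labels,
        entries=new_entries,
        directed=graph.directed,
        sizes={b: sizes[b] for b in new_labels},
        singleton={b: singleton[b] for b in new_labels},
    )


def load_density_json(path: str) -> DensityMatrix:
    """Inverse of :meth:`DensityMatrix.to_json`."""
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    entries = [
        [Fraction(c["numerator"], c["denominator"]) for c in row]
        for row in payload["entries"]
    ]
    return DensityMatrix(
        block_labels=list(payload["block_labels"]),
        entries=entries,
        directed=bool(payload["directed"]),
        sizes={b: int(n) for b, n in payload["sizes"].items()},
        singleton={b: bool(f) for b, f in payload["singleton"].items()},
    )
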