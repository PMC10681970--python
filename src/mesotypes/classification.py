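"""Rank-based classification of a community pair from its densities.

A pair of blocks (r, s) in canonical order (ω_rr ≥ ω_ss) is classified from
the consulted densities — three in the undirected case (ω_rr, ω_ss, ω_rs),
four in the directed case (ω_rr, ω_rs, ω_sr, ω_ss, with ω_rs the density of
links flowing r→s) — by strict inequalities only:

undirected::

    assortative      ω_rs < min(ω_rr, ω_ss)
    core-periphery   min(ω_rr, ω_ss) < ω_rs < max(ω_rr, ω_ss)
    disassortative   ω_rs > max(ω_rr, ω_ss)

directed::

    assortative      max(ω_rs, ω_sr) < min(ω_rr, ω_ss)
    core-periphery   min(ω_rr, ω_rs) > max(ω_sr, ω_ss)
    disassortative   min(ω_rs, ω_sr) > max(ω_rr, ω_ss)
    source-basin     min(ω_rr, ω_sr) > max(ω_rs, ω_ss)

Core–periphery and source–basin are the two mixed cases: one densely
self-connected block and one sparse block, distinguished by whether the
cross-block flow runs dense→sparse (core–periphery) or sparse→dense
(source–basin).

Any exact tie among consulted densities is DEGENERATE: the conditions above
are strict and the field has no convention for ties, so breaking them
silently would bias type fractions on sparse graphs where ties (especially
zeros) are common.  Densities should therefore be exact rationals (see
:mod:`mesotypes.density`); floats are accepted and compared exactly.

Strict orderings of the consulted values define the finer configuration
labels: 3 undirected configurations U1–U3 (one per type) and 12 directed
configurations D1–D12.  D-labels are indexed by lexicographic order of the
rank vector of (ω_rr, ω_rs, ω_sr, ω_ss), rank 1 = largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import permutations

from .density import DensityMatrix
from .errors import UsageError

logger = logging.getLogger(__name__)


class RelationshipType(str, Enum):
    ASSORTATIVE = "assortative"
    CORE_PERIPHERY = "core-periphery"
    DISASSORTATIVE = "disassortative"
    SOURCE_BASIN = "source-basin"
    DEGENERATE = "degenerate"


# The four named types, in reporting order.
TYPES = (
    RelationshipType.ASSORTATIVE,
    RelationshipType.CORE_PERIPHERY,
    RelationshipType.DISASSORTATIVE,
    RelationshipType.SOURCE_BASIN,
)


@dataclass(frozen=True)
class PairClassification:
    """Outcome of classifying one block pair (canonical order ω_rr ≥ ω_ss)."""

    pair: tuple
    configuration: str  # U1-U3, D1-D12, or DEGENERATE
    type: RelationshipType
    densities: dict  # consulted ω values keyed 'w_rr', 'w_ss', 'w_rs'[, 'w_sr']


def _directed_type(w_rr, w_rs, w_sr, w_ss) -> RelationshipType:
    if max(w_rs, w_sr) < min(w_rr, w_ss):
        return RelationshipType.ASSORTATIVE
    if min(w_rr, w_rs) > max(w_sr, w_ss):
        return RelationshipType.CORE_PERIPHERY
    if min(w_rs, w_sr) > max(w_rr, w_ss):
        return RelationshipType.DISASSORTATIVE
    if min(w_rr, w_sr) > max(w_rs, w_ss):
        return RelationshipType.SOURCE_BASIN
    raise AssertionError("strict ordering not covered by any condition")


def _rank_vector(values: tuple) -> tuple:
    """Ranks (1 = largest) of strictly distinct values, position-wise."""
    order = sorted(range(len(values)), key=lambda i: values[i], reverse=True)
    ranks = [0] * len(values)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return tuple(ranks)


def _build_directed_catalog() -> dict:
    """Map rank vector of (w_rr, w_rs, w_sr, w_ss) -> (D-label, type).

    Brute force over all 24 orderings of four distinct values; the canonical
    constraint w_rr > w_ss keeps 12.
    """
    valid = []
    for perm in permutations((4, 3, 2, 1)):
        w_rr, w_rs, w_sr, w_ss = perm
        if w_rr < w_ss:
            continue
        valid.append((_rank_vector(perm), _directed_type(w_rr, w_rs, w_sr, w_ss)))
    valid.sort(key=lambda item: item[0])
    return {rv: (f"D{i}", t) for i, (rv, t) in enumerate(valid, start=1)}


def _build_undirected_catalog() -> dict:
    """Map rank vector of (w_rr, w_ss, w_rs) -> (U-label, type)."""
    valid = []
    for perm in permutations((3, 2, 1)):
        w_rr, w_ss, w_rs = perm
        if w_rr < w_ss:
            continue
        if w_rs < w_ss:
            t = RelationshipType.ASSORTATIVE
        elif w_rs > w_rr:
            t = RelationshipType.DISASSORTATIVE
        else:
            t = RelationshipType.CORE_PERIPHERY
        valid.append((_rank_vector(perm), t))
    valid.sort(key=lambda item: item[0])
    return {rv: (f"U{i}", t) for i, (rv, t) in enumerate(valid, start=1)}


_DIRECTED_CATALOG = _build_directed_catalog()
_UNDIRECTED_CATALOG = _build_undirected_catalog()


def classify_pair_undirected(w_rr, w_ss, w_rs, pair: tuple = ("r", "s")) -> PairClassification:
    """Classify an undirected pair from its three consulted densities."""
    if w_rr < w_ss:
        raise UsageError("canonical order violated: requires w_rr >= w_ss")
    densities = {"w_rr": w_rr, "w_ss": w_ss, "w_rs": w_rs}
    if len({w_rr, w_ss, w_rs}) < 3:
        return PairClassification(pair, "DEGENERATE", RelationshipType.DEGENERATE, densities)
    label, t = _UNDIRECTED_CATALOG[_rank_vector((w_rr, w_ss, w_rs))]
    return PairClassification(pair, label, t, densities)


def classify_pair_directed(
    w_rr, w_rs, w_sr, w_ss, pair: tuple = ("r", "s")
) -> PairClassification:
    """Classify a directed pair; ``w_rs`` is the density of links r→s."""
    if w_rr < w_ss:
        raise UsageError("canonical order violated: requires w_rr >= w_ss")
    densities = {"w_rr": w_rr, "w_rs": w_rs, "w_sr": w_sr, "w_ss": w_ss}
    if len({w_rr, w_rs, w_sr, w_ss}) < 4:
        return PairClassification(pair, "DEGENERATE", RelationshipType.DEGENERATE, densities)
    label, t = _DIRECTED_CATALOG[_rank_vector((w_rr, w_rs, w_sr, w_ss))]
    return PairClassification(pair, label, t, densities)


def enumerate_configurations(directed: bool) -> list[tuple[str, RelationshipType]]:
    """All strict-ordering configurations with their types, in label order.

    Directed graphs admit 12 configurations (types with multiplicities
    assortative 2, core–periphery 4, disassortative 2, source–basin 4);
    undirected graphs admit 3, one per type.
    """
    catalog = _DIRECTED_CATALOG if directed else _UNDIRECTED_CATALOG
    return sorted(
        catalog.values(), key=lambda item: int(item[0][1:])
    )


def configuration_table(directed: bool) -> list[tuple[str, RelationshipType, tuple]]:
    """(label, type, rank vector) for every configuration, in label order.

    The rank vector gives the rank (1 = largest) of each consulted density,
    ordered (w_rr, w_rs, w_sr, w_ss) for directed and (w_rr, w_ss, w_rs) for
    undirected pairs.
    """
    catalog = _DIRECTED_CATALOG if directed else _UNDIRECTED_CATALOG
    rows = [(label, t, rv) for rv, (label, t) in catalog.items()]
    rows.sort(key=lambda row: int(row[0][1:]))
    return rows


def classify_all_pairs(omega: DensityMatrix) -> list[PairClassification]:
    """Classify every unordered block pair of a density matrix.

    Each pair is canonicalized by its own two self-densities before the
    inequalities are applied.  A pair touching a singleton block (flagged
    0/0 diagonal) is DEGENERATE.  Returns B(B−1)/2 classifications; an empty
    list (with a logged notice) when B < 2.
    """
    labels = omega.block_labels
    B = omega.B
    if B < 2:
        logger.info("density matrix has B=%d block(s); nothing to classify", B)
        return []
    out = []
    for i in range(B):
        for j in range(i + 1, B):
            r, s = labels[i], labels[j]
            w_ii, w_jj = omega.entries[i][i], omega.entries[j][j]
            if omega.is_singleton(r) or omega.is_singleton(s):
                densities = {"w_rr": w_ii, "w_ss": w_jj, "w_rs": omega.entries[i][j]}
                if omega.directed:
                    densities["w_sr"] = omega.entries[j][i]
                out.append(
                    PairClassification(
                        (r, s), "DEGENERATE", RelationshipType.DEGENERATE, densities
                    )
                )
                continue
            # per-pair canonical order: the denser block plays r
            if w_ii >= w_jj:
                a, b = i, j
                pair = (r, s)
            else:
                a, b = j, i
                pair = (s, r)
            if omega.directed:
                out.append(
                    classify_pair_directed(
                        omega.entries[a][a],
                        omega.entries[a][b],
                        omega.entries[b][a],
                        omega.entries[b][b],
                        pair=pair,
                    )
                )
            else:
                out.append(
                    classify_pair_undirected(
                        omega.entries[a][a],
                        omega.entries[b][b],
                        omega.entries[a][b],
                        pair=pair,
                    )
                )
    return out
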