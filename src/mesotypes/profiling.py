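"""Network-level type profiles and per-community role statistics.

``profile_network`` tallies the pairwise classifications of a whole density
matrix into exact type fractions; ``aggregate_survey`` summarizes profiles
across a collection of networks (which type dominates, which occurs, and the
spread of the nonassortative fraction per network category);
``community_summary`` reports the per-block role statistics used when
interpreting a source–basin pair (who holds the top out-degree nodes, mean
in/out degrees, attribute make-up).

Conventions for sparse inputs: DEGENERATE pairs count in the fraction
denominator but can never dominate, and the nonassortative fraction is taken
over classifiable (non-degenerate) pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .classification import (
    TYPES,
    PairClassification,
    RelationshipType,
    classify_all_pairs,
)
from .density import DensityMatrix
from .errors import CoverageError, UsageError
from .graph_model import Graph, Partition

logger = logging.getLogger(__name__)

TIE = "TIE"


@dataclass
class TypeProfile:
    """Type composition of one network's block pairs."""

    fractions: dict  # RelationshipType -> Fraction, sums to 1 over 5 categories
    occurrence: dict  # RelationshipType -> bool
    dominant: object  # RelationshipType or TIE
    dominant_set: tuple  # all argmax types (singleton unless TIE)
    n_pairs: int
    nonassortative_fraction: object  # Fraction, or None if no classifiable pair
    classifications: list = field(default_factory=list)


def _dominance(fractions: dict) -> tuple[object, tuple]:
    best = max(fractions[t] for t in TYPES)
    if best == 0:
        raise UsageError("all pairs are degenerate; no type can dominate")
    winners = tuple(t for t in TYPES if fractions[t] == best)
    return (winners[0] if len(winners) == 1 else TIE), winners


def profile_from_classifications(pairs: list[PairClassification]) -> TypeProfile:
    """Tally a list of pair classifications into a TypeProfile."""
    n = len(pairs)
    if n == 0:
        raise UsageError("profiling needs at least 2 blocks (no pairs to classify)")
    tally = {t: 0 for t in TYPES}
    tally[RelationshipType.DEGENERATE] = 0
    for p in pairs:
        tally[p.type] += 1
    fractions = {t: Fraction(c, n) for t, c in tally.items()}
    occurrence = {t: c > 0 for t, c in tally.items()}
    dominant, winners = _dominance(fractions)
    n_classifiable = n - tally[RelationshipType.DEGENERATE]
    if n_classifiable:
        nonassort = Fraction(
            n_classifiable - tally[RelationshipType.ASSORTATIVE], n_classifiable
        )
    else:
        nonassort = None
    return TypeProfile(
        fractions=fractions,
        occurrence=occurrence,
        dominant=dominant,
        dominant_set=winners,
        n_pairs=n,
        nonassortative_fraction=nonassort,
        classifications=pairs,
    )


def profile_network(omega: DensityMatrix) -> TypeProfile:
    """Classify all block pairs of ``omega`` and tally type fractions."""
    if omega.B < 2:
        raise UsageError(f"profiling needs >= 2 blocks, got B={omega.B}")
    return profile_from_classifications(classify_all_pairs(omega))


def dominant_type(profile: TypeProfile) -> tuple[object, tuple]:
    """(dominant type or TIE, tuple of all maximizers)."""
    return _dominance(profile.fractions)


def aggregate_survey(profiles: list[tuple]) -> dict:
    """Aggregate (network_id, category, TypeProfile) triples.

    Returns per type the fraction of networks in which it dominates and in
    which it occurs, and per category the five-number summary (min, Q1,
    median, Q3, max) of the per-network nonassortative fraction.
    """
    if not profiles:
        raise UsageError("aggregate_survey needs at least one profile")
    n = len(profiles)
    dominance = {t: 0 for t in TYPES}
    occurrence = {t: 0 for t in TYPES}
    by_category: dict = {}
    for net_id, category, prof in profiles:
        if prof.dominant != TIE:
            dominance[prof.dominant] += 1
        for t in TYPES:
            if prof.occurrence[t]:
                occurrence[t] += 1
        if prof.nonassortative_fraction is not None:
            by_category.setdefault(category, []).append(
                float(prof.nonassortative_fraction)
            )
    boxes = {}
    for cat, vals in by_category.items():
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        boxes[cat] = {
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            "n": len(vals),
        }
    return {
        "n_networks": n,
        "dominance_fraction": {t: Fraction(c, n) for t, c in dominance.items()},
        "occurrence_fraction": {t: Fraction(c, n) for t, c in occurrence.items()},
        "nonassortative_by_category": boxes,
    }


@dataclass
class CommunitySummary:
    """Role statistics of one block in a directed graph."""

    block: object
    size: int
    mean_in_degree: float
    mean_out_degree: float
    top_k_membership: int
    attribute_fractions: dict


def community_summary(
    graph: Graph,
    partition: Partition,
    k: int = 10,
    attributes: dict | None = None,
) -> list[CommunitySummary]:
    """Per-block size, mean degrees, top-k out-degree membership, attributes.

    Degrees are multiplicity-weighted.  The global top-k nodes are ranked by
    out-degree, ties at rank k broken by node label (and logged).  The
    attribute table is {node: {name: value}}; fractions are reported per
    (name, value) pair over the block members present in the table domain.
    """
    if not graph.directed:
        raise UsageError("community_summary needs a directed graph (in/out degrees)")
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    if attributes:
        unknown = set(attributes) - graph.nodes
        if unknown:
            raise CoverageError(
                f"attribute table names {len(unknown)} unknown node(s), "
                f"e.g. {sorted(map(str, unknown))[:5]}"
            )
    din, dout = graph.degrees()
    ranked = sorted(graph.nodes, key=lambda u: (-dout[u], str(u)))
    if len(ranked) > k and dout[ranked[k - 1]] == dout[ranked[k]]:
        logger.info("out-degree tie at rank %d broken by node label", k)
    top_k = set(ranked[:k])

    out = []
    for block in partition.block_labels:
        members = partition.members(block)
        nr = len(members)
        attr_fracs: dict = {}
        if attributes:
            counts: dict = {}
            covered = 0
            for u in members:
                if u in attributes:
                    covered += 1
                    for name, value in attributes[u].items():
                        key = (name, value)
                        counts[key] = counts.get(key, 0) + 1
            if covered:
                attr_fracs = {
                    f"{name}={value}": Fraction(c, covered)
                    for (name, value), c in sorted(counts.items())
                }
        out.append(
            CommunitySummary(
                block=block,
                size=nr,
                mean_in_degree=sum(din[u] for u in members) / nr,
                mean_out_degree=sum(dout[u] for u in members) / nr,
                top_k_membership=sum(1 for u in members if u in top_k),
                attribute_fractions=attr_fracs,
            )
        )
    return out
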