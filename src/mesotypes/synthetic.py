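"""Planted-partition generator: graphs whose expected density matrix is ω.

For every ordered (directed) or unordered (undirected) pair of distinct
nodes in blocks r, s the edge multiplicity is drawn independently as
Bernoulli(ω_rs) (simple graph, requires ω ≤ 1) or Poisson(ω_rs) (multigraph,
any ω ≥ 0).  Either way the expected empirical density of the sample equals
the planted ω entrywise, which makes the generator the natural test bed for
classification recovery: classify the sampled graph's empirical ω under the
true partition and compare with the type planted in ω.

Degree heterogeneity is deliberately not modelled — the classifier consumes
only ω, so targeting ω directly is the smallest sufficient test bed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .classification import RelationshipType, configuration_table
from .errors import UsageError
from .graph_model import Graph, Partition

BERNOULLI = "bernoulli"
POISSON = "poisson"


@dataclass
class PlantedSpec:
    """Target density matrix, block sizes, and sampling law."""

    omega: object  # B×B array-like of reals >= 0
    sizes: tuple
    directed: bool = True
    edge_model: str = BERNOULLI
    seed: int = 0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.sizes = tuple(int(n) for n in self.sizes)
        B = len(self.sizes)
        if self.omega.shape != (B, B):
            raise UsageError(
                f"omega shape {self.omega.shape} does not match {B} block sizes"
            )
        if any(n < 1 for n in self.sizes):
            raise UsageError("block sizes must be >= 1")
        if np.any(self.omega < 0):
            raise UsageError("omega entries must be >= 0")
        if self.edge_model == BERNOULLI:
            if np.any(self.omega > 1):
                raise UsageError(
                    "Bernoulli edge model requires omega <= 1; use the "
                    "Poisson model for multigraph densities above 1"
                )
        elif self.edge_model != POISSON:
            raise UsageError(f"unknown edge model: {self.edge_model!r}")
        if not self.directed and not np.allclose(self.omega, self.omega.T):
            raise UsageError("undirected omega must be symmetric")

    def to_dict(self) -> dict:
        return {
            "omega": self.omega.tolist(),
            "sizes": list(self.sizes),
            "directed": self.directed,
            "edge_model": self.edge_model,
            "seed": self.seed,
        }


def _draw(rng: np.random.Generator, p: float, shape: tuple, model: str) -> np.ndarray:
    if model == BERNOULLI:
        return (rng.random(shape) < p).astype(np.int64)
    return rng.poisson(p, shape)


def sample_planted(spec: PlantedSpec) -> tuple[Graph, Partition]:
    """Sample one graph from the planted spec; returns it with the truth.

    Node identifiers are the strings "0", "1", ... in block order; block
    labels are "1".."B".  Identical specs (including seed) reproduce
    identical graphs.
    """
    rng = np.random.default_rng(spec.seed)
    B = len(spec.sizes)
    offsets = np.concatenate([[0], np.cumsum(spec.sizes)])
    n_total = int(offsets[-1])
    names = [str(i) for i in range(n_total)]

    g = Graph(directed=spec.directed, nodes=set(names))
    assignment = {}
    for r in range(B):
        label = str(r + 1)
        for i in range(int(offsets[r]), int(offsets[r + 1])):
            assignment[names[i]] = label

    edges: dict = {}
    for r in range(B):
        nr = spec.sizes[r]
        s_range = range(B) if spec.directed else range(r, B)
        for s in s_range:
            ns = spec.sizes[s]
            p = float(spec.omega[r, s])
            m = _draw(rng, p, (nr, ns), spec.edge_model)
            if r == s:
                np.fill_diagonal(m, 0)
                if not spec.directed:
                    m = np.triu(m)
            ii, jj = np.nonzero(m)
            vals = m[ii, jj]
            off_r, off_s = int(offsets[r]), int(offsets[s])
            for a, b, v in zip(ii.tolist(), jj.tolist(), vals.tolist()):
                edges[(names[off_r + a], names[off_s + b])] = int(v)
    g._edges = edges
    return g, Partition(assignment)


def _rank_values(rank_vector: tuple, margin: float) -> list[float]:
    """Density for each consulted slot: rank k of n gets margin·(n+1−k)."""
    n = len(rank_vector)
    return [margin * (n + 1 - k) for k in rank_vector]


def planted_omega_for_configuration(
    configuration: str, margin: float, directed: bool = True
) -> np.ndarray:
    """2×2 ω realizing a configuration with consecutive rank gap = margin."""
    if margin <= 0:
        raise UsageError(f"margin must be > 0, got {margin}")
    for label, _t, rv in configuration_table(directed):
        if label == configuration:
            vals = _rank_values(rv, margin)
            if directed:
                w_rr, w_rs, w_sr, w_ss = vals
            else:
                w_rr, w_ss, w_rs = vals
                w_sr = w_rs
            return np.array([[w_rr, w_rs], [w_sr, w_ss]])
    raise UsageError(
        f"unknown {'directed' if directed else 'undirected'} "
        f"configuration: {configuration!r}"
    )


def fixture_for_configuration(
    config_type,
    margin: float,
    sizes: tuple = (300, 300),
    directed: bool = True,
    seed: int = 0,
    edge_model: str = BERNOULLI,
) -> tuple[Graph, Partition, RelationshipType]:
    """Sample a two-block graph planted to realize a type (or configuration).

    ``config_type`` is a :class:`RelationshipType` (a representative
    configuration of that type is used) or an explicit configuration label
    such as ``"D7"`` / ``"U2"``.  Consecutive ranked densities are separated
    by exactly ``margin``; with the Bernoulli model the largest density is
    4·margin (directed) or 3·margin (undirected), so margin must keep it ≤ 1.
    Returns (graph, true partition, planted type).
    """
    if len(sizes) != 2:
        raise UsageError("fixture_for_configuration builds two-block fixtures")
    table = configuration_table(directed)
    if isinstance(config_type, RelationshipType):
        matches = [label for label, t, _rv in table if t == config_type]
        if not matches:
            raise UsageError(
                f"type {config_type.value!r} is not realizable in "
                f"{'directed' if directed else 'undirected'} graphs"
            )
        configuration = matches[0]
    else:
        configuration = str(config_type)
    omega = planted_omega_for_configuration(configuration, margin, directed)
    planted_type = dict(
        (label, t) for label, t, _rv in table
    )[configuration]
    spec = PlantedSpec(
        omega=omega, sizes=sizes, directed=directed, edge_model=edge_model, seed=seed
    )
    graph, partition = sample_planted(spec)
    return graph, partition, planted_type


def write_manifest(path: str, spec: PlantedSpec, planted_type=None) -> None:
    payload = {"spec": spec.to_dict()}
    if planted_type is not None:
        payload["planted_type"] = getattr(planted_type, "value", str(planted_type))
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
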