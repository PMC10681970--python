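"""Type fractions expected under a random edge-density matrix.

The baseline draws every entry of a B×B matrix ω i.i.d. Uniform(0, 1)
(upper-triangle draw mirrored when undirected), canonicalizes each pair, and
classifies all pairs.  Because the classifier only consults rankings, any
continuous i.i.d. law would give identical type fractions; Uniform(0, 1) is
used for concreteness.  For B = 2 the exact per-pair probabilities follow by
counting configurations: directed (A, CP, D, SB) = (2, 4, 2, 4)/12; undirected
(A, CP, D) = (1, 1, 1)/3.  Ties have probability zero under a continuous law,
so the DEGENERATE fraction is almost surely 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import TYPES, RelationshipType, classify_pair_directed, classify_pair_undirected
from .errors import UsageError

_CATEGORIES = TYPES + (RelationshipType.DEGENERATE,)


@dataclass
class NullEstimate:
    """Monte-Carlo mean/std of per-network type fractions under the null."""

    B: int
    directed: bool
    n_samples: int
    seed: int
    mean: dict  # RelationshipType -> float
    std: dict  # RelationshipType -> float (spread across replicates)
    std_error: dict  # RelationshipType -> float (std / sqrt(n_samples))

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "directed": self.directed,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "mean_fraction": {t.value: self.mean[t] for t in _CATEGORIES},
            "std": {t.value: self.std[t] for t in _CATEGORIES},
            "std_error": {t.value: self.std_error[t] for t in _CATEGORIES},
        }


def _classify_matrix_pairs(m: np.ndarray, directed: bool) -> dict:
    """Per-type pair fractions of one sampled ω matrix."""
    B = m.shape[0]
    tally = {t: 0 for t in _CATEGORIES}
    n_pairs = 0
    for i in range(B):
        for j in range(i + 1, B):
            n_pairs += 1
            if m[i, i] >= m[j, j]:
                a, b = i, j
            else:
                a, b = j, i
            if directed:
                c = classify_pair_directed(m[a, a], m[a, b], m[b, a], m[b, b])
            else:
                c = classify_pair_undirected(m[a, a], m[b, b], m[a, b])
            tally[c.type] += 1
    return {t: tally[t] / n_pairs for t in _CATEGORIES}


def null_profile(B: int, directed: bool, n_samples: int, seed: int) -> NullEstimate:
    """Monte-Carlo null: random ω replicates, classified and averaged.

    Reproducible: the same seed gives bit-identical estimates.
    """
    if B < 2:
        raise UsageError(f"null model needs B >= 2, got {B}")
    if n_samples < 1:
        raise UsageError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(n_samples, B, B))
    fracs = np.empty((n_samples, len(_CATEGORIES)))
    for k in range(n_samples):
        m = draws[k]
        if not directed:
            m = np.triu(m) + np.triu(m, 1).T
        f = _classify_matrix_pairs(m, directed)
        fracs[k] = [f[t] for t in _CATEGORIES]
    mean = fracs.mean(axis=0)
    std = fracs.std(axis=0, ddof=0)
    return NullEstimate(
        B=B,
        directed=directed,
        n_samples=n_samples,
        seed=seed,
        mean={t: float(mean[i]) for i, t in enumerate(_CATEGORIES)},
        std={t: float(std[i]) for i, t in enumerate(_CATEGORIES)},
        std_error={
            t: float(std[i] / np.sqrt(n_samples)) for i, t in enumerate(_CATEGORIES)
        },
    )
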