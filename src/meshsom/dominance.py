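"""Per-neuron term dominance and ordinal term rankings.

Term dominance of term ``k`` at neuron ``i`` is the share of that neuron's
total weight carried by the term: ``d_ik = w_ik / sum_k w_ik``.  Ranking the
terms of a neuron by descending dominance gives the neuron its ordinal label
sequence: the rank-1 term is the neuron's top label, the rank-2 term its
runner-up, and so on.  These rankings are the substrate of patch clustering,
label placement, and transect analytics.

Ties (measure-zero with real-valued trained weights, but common in degenerate
test inputs) break toward the term with the higher corpus document frequency,
then lexicographically -- which is exactly ascending canonical vocabulary
index, so a stable sort on descending dominance suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import TermVocabulary
from .trainer import SOMModel

__all__ = ["DominanceRanking", "dominance_matrix", "top_terms_table"]


@dataclass
class DominanceRanking:
    vocabulary: TermVocabulary
    dominance: np.ndarray  # (n_neurons, n_terms), rows sum to 1 when valid
    ranked_terms: np.ndarray  # (n_neurons, max_rank) vocab indices, -1 if degenerate
    degenerate: np.ndarray  # (n_neurons,) bool: all-zero weight rows
    max_rank_materialized: int

    @property
    def n_neurons(self) -> int:
        return self.dominance.shape[0]

    def full_ranking(self, neurons: np.ndarray) -> np.ndarray:
        """Full term ordering (all ranks) for the given neurons."""
        return np.argsort(-self.dominance[neurons], axis=1, kind="stable")


def dominance_matrix(model: SOMModel, max_rank: int = 10) -> DominanceRanking:
    """Row-normalize model weights into dominance and materialize rankings.

    Neurons whose weight row is all zero (possible only if never updated from
    an all-zero initialization row) are flagged degenerate: their dominance
    row is zero and their ranked terms are -1, and downstream clustering
    excludes them.
    """
    w = model.weights
    if not np.all(np.isfinite(w)):
        raise ValueError("model weights contain non-finite values")
    sums = w.sum(axis=1)
    degenerate = sums <= 0
    dom = np.zeros_like(w)
    ok = ~degenerate
    dom[ok] = w[ok] / sums[ok, None]
    max_rank = min(max_rank, w.shape[1])
    # stable sort on descending dominance; canonical vocab index breaks ties
    ranked = np.argsort(-dom, axis=1, kind="stable")[:, :max_rank].astype(np.int64)
    ranked[degenerate] = -1
    return DominanceRanking(
        vocabulary=model.vocabulary,
        dominance=dom,
        ranked_terms=ranked,
        degenerate=degenerate,
        max_rank_materialized=max_rank,
    )


def top_terms_table(
    ranking: DominanceRanking, neuron: int, k: int
) -> pd.DataFrame:
    """The ``k`` highest-dominance terms of one neuron, in rank order.

    Columns: ``rank`` (1-based), ``term``, ``dominance``.
    """
    if not 0 <= neuron < ranking.n_neurons:
        raise IndexError(f"neuron index {neuron} out of range")
    if k > ranking.max_rank_materialized:
        raise ValueError(
            f"k={k} exceeds materialized ranks ({ranking.max_rank_materialized})"
        )
    if ranking.degenerate[neuron]:
        return pd.DataFrame(columns=["rank", "term", "dominance"])
    idx = ranking.ranked_terms[neuron, :k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "term": [ranking.vocabulary.terms[j] for j in idx],
            "dominance": ranking.dominance[neuron, idx],
        }
    )
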