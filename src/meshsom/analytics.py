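"""Map-reading instruments: transects, rank transitions, document overlays.

A *transect* is an ordered path of lattice-adjacent neurons through the map;
reading the dominance values of the rank-1..R terms along it profiles how
topical regions rise, peak, and hand over to their neighbors.  The *rank
transition* series track, for every term that reaches the top ranks anywhere
on the path, its ordinal rank at each step -- revealing terms that plummet
out of sight once demoted versus terms that linger near the top.

The *base map overlay* places an arbitrary set of documents (e.g. all
documents matching a term query) onto the trained lattice using the exact
BMU rule from training (same cosine, same lowest-index tie-break), tallying
per-neuron match counts for proportional-symbol display.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .dominance import DominanceRanking
from .lattice import HexLattice
from .trainer import SOMModel, bmu_batch

__all__ = [
    "Transect",
    "OverlayResult",
    "build_transect",
    "transect_profiles",
    "query_documents",
    "overlay_documents",
]


@dataclass
class Transect:
    path: np.ndarray  # ordered neuron indices, consecutive pairs adjacent
    profiles: np.ndarray  # (max_rank, len(path)) dominance of rank-r term
    transitions: pd.DataFrame  # columns: step, term, rank (NaN when > depth)
    terms: list[str]  # terms reaching the top ranks anywhere on the path


def _bfs_path(lattice: HexLattice, start: int, goal: int) -> list[int]:
    """Shortest hex-grid path; BFS visiting neighbors in ascending index."""
    if start == goal:
        return [start]
    parent = {start: -1}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in lattice.neighbors(u):
            if v not in parent:
                parent[v] = u
                if v == goal:
                    path = [v]
                    while parent[path[-1]] != -1:
                        path.append(parent[path[-1]])
                    return path[::-1]
                q.append(v)
    raise ValueError(f"no path from {start} to {goal}")  # unreachable


def build_transect(lattice: HexLattice, waypoints: list[int]) -> np.ndarray:
    """Shortest lattice path through the waypoints, in order."""
    if len(waypoints) < 2:
        raise ValueError("need at least 2 waypoints")
    for w in waypoints:
        if not 0 <= w < lattice.n_neurons:
            raise IndexError(f"waypoint {w} out of range")
    path: list[int] = []
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = _bfs_path(lattice, int(a), int(b))
        path.extend(seg if not path else seg[1:])
    return np.array(path, dtype=np.int64)


def transect_profiles(
    ranking: DominanceRanking, path: np.ndarray, max_rank: int = 3
) -> Transect:
    """Dominance profiles and rank-transition series along a transect path."""
    path = np.asarray(path, dtype=np.int64)
    full = ranking.full_ranking(path)  # (steps, n_terms) term indices by rank
    dom = ranking.dominance[path]
    steps = len(path)
    profiles = np.zeros((max_rank, steps))
    for r in range(max_rank):
        profiles[r] = dom[np.arange(steps), full[:, r]]

    # terms reaching rank <= max_rank at any step, in order of appearance
    seen: dict[int, None] = {}
    for s in range(steps):
        for r in range(max_rank):
            seen.setdefault(int(full[s, r]), None)
    term_idx = list(seen)
    # ordinal rank (1-based) of each tracked term at each step
    rank_of = np.empty((steps, len(term_idx)), dtype=np.int64)
    pos = np.empty_like(full)
    ar = np.arange(full.shape[1])
    for s in range(steps):
        pos[s, full[s]] = ar
    for j, t in enumerate(term_idx):
        rank_of[:, j] = pos[:, t] + 1
    rows = [
        {"step": s, "term": ranking.vocabulary.terms[t], "rank": int(rank_of[s, j])}
        for j, t in enumerate(term_idx)
        for s in range(steps)
    ]
    transitions = pd.DataFrame(rows, columns=["step", "term", "rank"])
    return Transect(
        path=path,
        profiles=profiles,
        transitions=transitions,
        terms=[ranking.vocabulary.terms[t] for t in term_idx],
    )


def query_documents(corpus: Corpus, terms: list[str], mode: str = "all") -> list[str]:
    """Documents containing all (or any) of the query terms."""
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    idx = {corpus.vocabulary.index_of(t) for t in terms}  # KeyError names term
    out = []
    for doc_id, doc in zip(corpus.doc_ids, corpus.documents):
        present = idx.issubset(doc) if mode == "all" else bool(idx & set(doc.tolist()))
        if present:
            out.append(doc_id)
    return out


@dataclass
class OverlayResult:
    per_neuron_counts: np.ndarray  # (n_neurons,) int
    total_matches: int

    def to_frame(self) -> pd.DataFrame:
        nz = np.nonzero(self.per_neuron_counts)[0]
        return pd.DataFrame(
            {"neuron": nz, "count": self.per_neuron_counts[nz]}
        )


def overlay_documents(
    model: SOMModel, corpus: Corpus, doc_ids: list[str]
) -> OverlayResult:
    """BMU-map a document subset and tally per-neuron counts.

    Documents share the model's vocabulary; an empty list yields an empty
    overlay.  Uses the training BMU rule unchanged.
    """
    if len(corpus.vocabulary) != len(model.vocabulary):
        raise ValueError("corpus and model vocabularies differ in size")
    counts = np.zeros(model.lattice.n_neurons, dtype=np.int64)
    if not doc_ids:
        return OverlayResult(per_neuron_counts=counts, total_matches=0)
    by_id = {}
    for i, d in enumerate(corpus.doc_ids):
        by_id.setdefault(d, i)
    rows = [by_id[d] for d in doc_ids]  # KeyError on unknown id
    X = corpus.occurrence_matrix()[rows]
    bmus, _ = bmu_batch(model.weights, model.weight_norms(), X)
    np.add.at(counts, bmus, 1)
    return OverlayResult(per_neuron_counts=counts, total_matches=len(rows))
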