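"""Neuron label clustering: contiguous same-label patches per dominance rank.

If two lattice-adjacent neurons share the same rank-r dominant term, their
boundary is dissolved; the maximal connected sets that result are *patches*
(neuron label clusters).  Because a single term drives each patch's creation,
that term is the patch's label.  Clustering is repeated independently per
dominance rank, producing one patch layer per rank level -- lower-rank layers
are not refinements of higher ones.

Patch geometry is the union of the member neurons' hexagon cells (dissolved
with shapely), so a patch's polygon area is exactly ``|neurons| x hex area``,
with holes where foreign neurons are enclosed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .corpus import Corpus
from .dominance import DominanceRanking
from .lattice import HexLattice

__all__ = [
    "Patch",
    "PatchSet",
    "extract_patches",
    "level_stats",
    "term_area_stats",
    "dissolve_geometry",
    "patchset_geojson",
]


@dataclass
class Patch:
    patch_id: int
    rank_level: int
    term: int  # vocabulary index; the patch's label by construction
    neurons: np.ndarray  # sorted member neuron indices
    _polygon: Polygon | MultiPolygon | None = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)


@dataclass
class PatchSet:
    rank_level: int
    patches: list[Patch]
    vocabulary_terms: tuple[str, ...]

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def n_unique_terms(self) -> int:
        return len({p.term for p in self.patches})

    def term_name(self, patch: Patch) -> str:
        return self.vocabulary_terms[patch.term]


def extract_patches(
    ranking: DominanceRanking, lattice: HexLattice, rank_level: int
) -> PatchSet:
    """Connected components of equal rank-level labels under hex adjacency.

    Degenerate (all-zero) neurons are excluded.  Patches are ordered by their
    lowest member neuron index, which fixes patch ids reproducibly.
    """
    if not 1 <= rank_level <= ranking.max_rank_materialized:
        raise ValueError(
            f"rank_level {rank_level} outside materialized range "
            f"[1, {ranking.max_rank_materialized}]"
        )
    n = lattice.n_neurons
    if ranking.n_neurons != n:
        raise ValueError("ranking and lattice neuron counts differ")
    labels = ranking.ranked_terms[:, rank_level - 1]
    valid = ~ranking.degenerate

    pairs = lattice.adjacency_pairs()
    keep = (
        valid[pairs[:, 0]]
        & valid[pairs[:, 1]]
        & (labels[pairs[:, 0]] == labels[pairs[:, 1]])
    )
    e = pairs[keep]
    graph = sp.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)

    patches: list[Patch] = []
    order = np.argsort(comp, kind="stable")
    bounds = np.searchsorted(comp[order], np.arange(n_comp + 1))
    for c in range(n_comp):
        members = order[bounds[c] : bounds[c + 1]]
        members = members[valid[members]]
        if len(members) == 0:
            continue
        patches.append(
            Patch(
                patch_id=-1,
                rank_level=rank_level,
                term=int(labels[members[0]]),
                neurons=np.sort(members),
            )
        )
    patches.sort(key=lambda p: int(p.neurons[0]))
    for i, p in enumerate(patches):
        p.patch_id = i
    return PatchSet(
        rank_level=rank_level,
        patches=patches,
        vocabulary_terms=ranking.vocabulary.terms,
    )


def dissolve_geometry(patch: Patch, lattice: HexLattice) -> Polygon | MultiPolygon:
    """Union of the member hexagon cells (cached on the patch)."""
    if len(patch.neurons) == 0:
        raise ValueError("empty patch")
    if patch._polygon is None:
        patch._polygon = unary_union(
            [lattice.hex_polygon(int(i)) for i in patch.neurons]
        )
    return patch._polygon


def level_stats(patchsets: list["PatchSet"]) -> pd.DataFrame:
    """Per-level unique label terms and patch counts (label-accounting table)."""
    rows = [
        {
            "level": ps.rank_level,
            "unique_terms": ps.n_unique_terms,
            "patch_count": ps.n_patches,
        }
        for ps in patchsets
    ]
    return pd.DataFrame(rows, columns=["level", "unique_terms", "patch_count"])


def term_area_stats(
    patchsets: list["PatchSet"],
    corpus: Corpus | None = None,
    sort_by: str = "neurons",
) -> pd.DataFrame:
    """Per-term map occupancy at rank level 1.

    Columns: ``term``, ``neuron_count`` (neurons where the term is dominant),
    ``patch_count`` (contiguous patches), ``doc_count`` (corpus document
    frequency, when a corpus is given).  Sorted by ``sort_by`` in
    {"neurons", "patches"}, descending -- the two orderings show that corpus
    frequency does not directly predict occupied map area.
    """
    level1 = next((ps for ps in patchsets if ps.rank_level == 1), None)
    if level1 is None:
        raise ValueError("no level-1 patch set present")
    agg: dict[int, list[int]] = {}
    for p in level1.patches:
        entry = agg.setdefault(p.term, [0, 0])
        entry[0] += p.n_neurons
        entry[1] += 1
    # terms absent from level 1 are reported with zero counts
    names = {level1.vocabulary_terms[t]: c for t, c in agg.items()}
    universe = (
        list(corpus.vocabulary.terms) if corpus is not None else list(names)
    )
    rows = []
    for name in universe:
        n_neurons, n_patches = names.get(name, (0, 0))
        row = {
            "term": name,
            "neuron_count": n_neurons,
            "patch_count": n_patches,
        }
        if corpus is not None:
            row["doc_count"] = (
                int(corpus.vocabulary.doc_frequency[corpus.vocabulary.index_of(name)])
                if name in corpus.vocabulary
                else 0
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    key = {"neurons": "neuron_count", "patches": "patch_count"}.get(sort_by)
    if key is None:
        raise ValueError("sort_by must be 'neurons' or 'patches'")
    return df.sort_values(
        [key, "term"], ascending=[False, True], ignore_index=True
    )


def patchset_geojson(patchset: PatchSet, lattice: HexLattice) -> dict:
    """GeoJSON FeatureCollection: one Feature per patch, lattice-plane coords."""
    features = []
    for p in patchset.patches:
        geom = dissolve_geometry(p, lattice)
        features.append(
            {
                "type": "Feature",
                "geometry": geom.__geo_interface__,
                "properties": {
                    "level": patchset.rank_level,
                    "term": patchset.term_name(p),
                    "neuron_count": p.n_neurons,
                    "patch_id": p.patch_id,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
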