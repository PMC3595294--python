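"""Synthetic MeSH-like corpora with known latent topical structure.

The generator emulates the statistical features of an indexer-assigned
controlled-vocabulary corpus that the map pipeline depends on:

* very sparse binary documents, with terms-per-document following a shifted
  negative binomial calibrated to mean 7.06 and SD 3.67 (the family is chosen
  because the real corpus shows mean > median, a large SD, a hard floor of
  one term, and tens of thousands of single-term documents);
* a latent hard topic per document, each topic owning a contiguous block of
  topic-exclusive terms, with optional leakage into neighboring blocks;
* a small stratum of high-frequency "methodological" terms (procedural
  headings like "Time Factors" in the real data) drawn across all topics with
  Zipf-decaying weights, so the most frequent terms in the corpus co-occur
  with every topic rather than marking any one of them.

Ground-truth topic labels are returned so that downstream topology tests can
check that training places same-topic documents near each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus

__all__ = ["SyntheticSpec", "GroundTruth", "generate_corpus", "write_ground_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus generator.

    ``methodological_fraction`` is the per-slot probability that a term is
    drawn from the shared methodological stratum; the stratum itself holds
    ``methodological_vocab_fraction`` of the vocabulary (a small set of very
    frequent cross-topic terms, mirroring the handful of procedural headings
    that top real frequency tables).  At the defaults the most frequent
    procedural term lands in roughly a tenth of all documents -- a few times
    the rate of the busiest topic-exclusive term -- so procedural terms rise
    to the top of the frequency table and dominate boundary neurons without
    swamping the topical regions themselves.
    """

    n_docs: int = 10_000
    vocab_size: int = 500
    n_topics: int = 10
    topic_vocab_overlap: float = 0.1
    methodological_fraction: float = 0.05
    methodological_vocab_fraction: float = 0.04
    zipf_exponent: float = 1.0
    doclen_mean: float = 7.06
    doclen_sd: float = 3.67
    doclen_min: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if not 1 <= self.n_topics <= self.vocab_size:
            raise ValueError("need 1 <= n_topics <= vocab_size")
        if not 0.0 <= self.topic_vocab_overlap <= 1.0:
            raise ValueError("topic_vocab_overlap must be in [0, 1]")
        if not 0.0 <= self.methodological_fraction <= 1.0:
            raise ValueError("methodological_fraction must be in [0, 1]")
        if not 0.0 <= self.methodological_vocab_fraction < 1.0:
            raise ValueError("methodological_vocab_fraction must be in [0, 1)")
        if self.doclen_min < 1:
            raise ValueError("doclen_min must be >= 1")
        if self.doclen_mean <= self.doclen_min:
            raise ValueError(
                "infeasible document length parameterization: "
                f"mean {self.doclen_mean} <= min {self.doclen_min}"
            )
        if self.doclen_sd <= 0:
            raise ValueError("doclen_sd must be > 0")
        n_meth = round(self.methodological_vocab_fraction * self.vocab_size)
        if self.vocab_size - n_meth < self.n_topics:
            raise ValueError(
                "vocabulary too small for the requested topic count after "
                "reserving the methodological stratum"
            )


@dataclass
class GroundTruth:
    """Latent structure behind a generated corpus."""

    topics: np.ndarray  # per-document topic index, aligned with corpus.doc_ids
    methodological_terms: list[str]
    topic_terms: list[list[str]]  # per topic, its exclusive term block


def _doclen_params(spec: SyntheticSpec) -> tuple[float, float]:
    """Negative-binomial (n, p) for the shifted length L - doclen_min.

    Moment matching: the shift leaves the variance untouched, so with
    m = mean - min and v = sd^2 we need v > m (overdispersion) and then
    n = m^2 / (v - m), p = n / (n + m).
    """
    m = spec.doclen_mean - spec.doclen_min
    v = spec.doclen_sd**2
    if v <= m:
        raise ValueError(
            "infeasible document length parameterization: variance "
            f"{v:.4g} must exceed mean-above-minimum {m:.4g} for a "
            "negative-binomial length model"
        )
    n = m * m / (v - m)
    p = n / (n + m)
    return n, p


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus from the generative model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    V = spec.vocab_size
    n_meth = round(spec.methodological_vocab_fraction * V)
    n_topic_terms = V - n_meth
    blocks = np.array_split(np.arange(n_topic_terms), spec.n_topics)

    width = len(str(V))
    meth_terms = [f"proc-{j:0{width}d}" for j in range(n_meth)]
    topic_terms: list[list[str]] = []
    all_names: list[str] = list(meth_terms)
    for t, block in enumerate(blocks):
        terms_t = [f"topic{t:02d}-{j:0{width}d}" for j in range(len(block))]
        topic_terms.append(terms_t)
        all_names.extend(terms_t)

    # Zipf weights inside the methodological stratum; topic blocks uniform.
    if n_meth:
        meth_w = 1.0 / np.arange(1, n_meth + 1) ** spec.zipf_exponent
        meth_w /= meth_w.sum()
    meth_ids = np.arange(n_meth)
    block_ids = [n_meth + b for b in blocks]

    nb_n, nb_p = _doclen_params(spec)
    lengths = spec.doclen_min + rng.negative_binomial(nb_n, nb_p, size=spec.n_docs)
    topics = rng.integers(0, spec.n_topics, size=spec.n_docs)

    doc_ids = [f"doc{d:07d}" for d in range(spec.n_docs)]
    term_lists: list[list[str]] = []
    for d in range(spec.n_docs):
        L = int(min(lengths[d], V))
        t = int(topics[d])
        own = block_ids[t]
        if spec.n_topics > 1 and spec.topic_vocab_overlap > 0:
            nbr = np.concatenate(
                [
                    block_ids[(t - 1) % spec.n_topics],
                    block_ids[(t + 1) % spec.n_topics],
                ]
            )
            nbr = np.unique(nbr[~np.isin(nbr, own)])
        else:
            nbr = np.zeros(0, dtype=np.int64)

        k_meth = int(rng.binomial(L, spec.methodological_fraction)) if n_meth else 0
        k_meth = min(k_meth, n_meth)
        k_topic = L - k_meth
        k_leak = (
            int(rng.binomial(k_topic, spec.topic_vocab_overlap)) if len(nbr) else 0
        )
        k_leak = min(k_leak, len(nbr))
        k_own = min(k_topic - k_leak, len(own))

        chosen: list[np.ndarray] = []
        if k_meth:
            chosen.append(rng.choice(meth_ids, size=k_meth, replace=False, p=meth_w))
        if k_own:
            chosen.append(rng.choice(own, size=k_own, replace=False))
        if k_leak:
            chosen.append(rng.choice(nbr, size=k_leak, replace=False))
        idx = np.concatenate(chosen) if chosen else np.zeros(0, dtype=np.int64)
        if len(idx) == 0:  # degenerate clamps; fall back to one own-block term
            idx = rng.choice(own, size=1, replace=False)
        term_lists.append([all_names[int(j)] for j in idx])

    corpus = Corpus.from_term_lists(doc_ids, term_lists)
    return corpus, GroundTruth(
        topics=topics, methodological_terms=meth_terms, topic_terms=topic_terms
    )


def write_ground_truth(truth: GroundTruth, doc_ids: list[str], path: str) -> None:
    """Write the per-document topic labels as ``doc_id<TAB>topic`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, t in zip(doc_ids, truth.topics):
            fh.write(f"{doc_id}\t{int(t)}\n")
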