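"""Sparse binary term-document corpora.

A corpus is a collection of documents, each represented by the *set* of
controlled-vocabulary terms (e.g. MeSH headings) assigned to it by an
indexer.  Occurrence is binary -- a term is either present or absent -- and
documents are very sparse relative to the vocabulary (a handful of terms per
document against thousands of vocabulary entries), so each document is stored
as a sorted array of vocabulary indices rather than a dense vector.

Vocabulary order is canonical throughout the package: terms are sorted by
descending document frequency, ties broken lexicographically.  This makes
"keep the N most frequent terms" a prefix operation and gives every
downstream tie-break (dominance ranking, labeling) a deterministic meaning.

Two on-disk dialects are supported:

* TSV: one document per line, ``doc_id<TAB>term1|term2|...``, UTF-8, no header.
* Matrix Market: a coordinate-format pattern matrix (rows = documents,
  columns = terms) named ``<base>.mtx``, with sibling files
  ``<base>.vocab.txt`` (one term per line) and ``<base>.docids.txt``
  (one document id per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "TermVocabulary",
    "Corpus",
    "CorpusStats",
    "read_corpus",
    "write_corpus",
    "filter_top_terms",
    "corpus_stats",
]


@dataclass(frozen=True)
class TermVocabulary:
    """Ordered vocabulary with per-term document frequencies.

    ``terms[i]`` is the i-th term in canonical order; ``doc_frequency[i]``
    counts the documents containing it.  Use :meth:`from_counts` to build a
    vocabulary in canonical order from raw counts.
    """

    terms: tuple[str, ...]
    doc_frequency: np.ndarray  # int64, same length as terms
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.doc_frequency):
            raise ValueError("terms and doc_frequency lengths differ")
        index = {t: i for i, t in enumerate(self.terms)}
        if len(index) != len(self.terms):
            raise ValueError("vocabulary terms are not unique")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "TermVocabulary":
        """Build a vocabulary in canonical order (freq desc, term asc)."""
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        terms = tuple(t for t, _ in ordered)
        freq = np.array([c for _, c in ordered], dtype=np.int64)
        return cls(terms, freq)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def index_of(self, term: str) -> int:
        try:
            return self._index[term]
        except KeyError:
            raise KeyError(f"term not in vocabulary: {term!r}") from None

    def sha1(self) -> str:
        """Stable hash of the term list, used to fingerprint trained models."""
        import hashlib

        h = hashlib.sha1()
        for t in self.terms:
            h.update(t.encode("utf-8"))
            h.update(b"\n")
        return h.hexdigest()


@dataclass
class Corpus:
    """Binary term-document corpus over a canonical :class:`TermVocabulary`."""

    vocabulary: TermVocabulary
    doc_ids: list[str]
    documents: list[np.ndarray]  # per doc: sorted unique int32 vocab indices

    def __post_init__(self) -> None:
        if len(self.doc_ids) != len(self.documents):
            raise ValueError("doc_ids and documents lengths differ")

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)

    @classmethod
    def from_term_lists(
        cls, doc_ids: list[str], term_lists: list[list[str]]
    ) -> "Corpus":
        """Build a corpus from per-document term string lists.

        Duplicate term mentions within a document collapse to a single
        occurrence; the vocabulary is canonicalized from observed frequencies.
        """
        sets = [sorted(set(ts)) for ts in term_lists]
        counts: dict[str, int] = {}
        for ts in sets:
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        vocab = TermVocabulary.from_counts(counts)
        docs = [
            np.array(sorted(vocab.index_of(t) for t in ts), dtype=np.int32)
            for ts in sets
        ]
        return cls(vocab, list(doc_ids), docs)

    def occurrence_matrix(self) -> sp.csr_matrix:
        """Documents x terms binary matrix (float64 ones)."""
        indptr = np.zeros(self.n_docs + 1, dtype=np.int64)
        lens = np.fromiter(
            (len(d) for d in self.documents), dtype=np.int64, count=self.n_docs
        )
        np.cumsum(lens, out=indptr[1:])
        if self.documents:
            indices = np.concatenate(self.documents).astype(np.int32)
        else:
            indices = np.zeros(0, dtype=np.int32)
        data = np.ones(len(indices), dtype=np.float64)
        return sp.csr_matrix(
            (data, indices, indptr), shape=(self.n_docs, self.n_terms)
        )

    def recomputed_doc_frequency(self) -> np.ndarray:
        freq = np.zeros(self.n_terms, dtype=np.int64)
        for d in self.documents:
            freq[d] += 1
        return freq


@dataclass(frozen=True)
class CorpusStats:
    n_docs: int
    n_terms: int
    mean_terms: float
    median_terms: float
    sd_terms: float  # population SD
    min_terms: int
    max_terms: int


def read_corpus(path: str, format: str = "tsv") -> Corpus:
    """Read a corpus in the TSV or Matrix Market dialect.

    For ``format="matrixmarket"``, *path* names the ``.mtx`` file and the
    sibling ``<base>.vocab.txt`` / ``<base>.docids.txt`` files are read
    alongside it.  The vocabulary is re-canonicalized on read.
    """
    if format == "tsv":
        doc_ids: list[str] = []
        term_lists: list[list[str]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ValueError(
                        f"{path}: malformed line {lineno}: expected "
                        "'doc_id<TAB>term1|term2|...'"
                    )
                terms = [t for t in parts[1].split("|") if t]
                if not terms:
                    raise ValueError(
                        f"{path}: malformed line {lineno}: empty term list"
                    )
                doc_ids.append(parts[0])
                term_lists.append(terms)
        return Corpus.from_term_lists(doc_ids, term_lists)
    if format == "matrixmarket":
        base = path[:-4] if path.endswith(".mtx") else path
        mat = sp.csr_matrix(scipy.io.mmread(path))
        with open(base + ".vocab.txt", encoding="utf-8") as fh:
            terms = [line.rstrip("\n") for line in fh if line.strip()]
        with open(base + ".docids.txt", encoding="utf-8") as fh:
            doc_ids = [line.rstrip("\n") for line in fh if line.strip()]
        if mat.shape != (len(doc_ids), len(terms)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(doc_ids)} doc ids x {len(terms)} vocabulary terms"
            )
        term_lists = [
            [terms[j] for j in mat.indices[mat.indptr[i] : mat.indptr[i + 1]]]
            for i in range(mat.shape[0])
        ]
        return Corpus.from_term_lists(doc_ids, term_lists)
    raise ValueError(f"unknown corpus format: {format!r}")


def write_corpus(corpus: Corpus, path: str, format: str = "tsv") -> None:
    """Write a corpus in the TSV or Matrix Market dialect (see module docs)."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for doc_id, idx in zip(corpus.doc_ids, corpus.documents):
                terms = "|".join(corpus.vocabulary.terms[j] for j in idx)
                fh.write(f"{doc_id}\t{terms}\n")
        return
    if format == "matrixmarket":
        base = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(
            base + ".mtx", corpus.occurrence_matrix().tocoo(), field="pattern"
        )
        with open(base + ".vocab.txt", "w", encoding="utf-8") as fh:
            fh.writelines(t + "\n" for t in corpus.vocabulary.terms)
        with open(base + ".docids.txt", "w", encoding="utf-8") as fh:
            fh.writelines(d + "\n" for d in corpus.doc_ids)
        return
    raise ValueError(f"unknown corpus format: {format!r}")


def filter_top_terms(
    corpus: Corpus, keep: int, min_doc_frequency: int = 0
) -> tuple[Corpus, int]:
    """Restrict the corpus to its ``keep`` most frequent terms.

    The cut is a prefix of the canonical vocabulary order (descending
    frequency, lexicographic tie-break).  ``min_doc_frequency`` optionally
    drops rarer terms first, emulating an upstream rare-term pre-filter.
    Documents emptied by the cut are dropped.

    Returns ``(filtered_corpus, n_dropped_documents)``.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if keep > len(corpus.vocabulary):
        raise ValueError(
            f"keep={keep} exceeds vocabulary size {len(corpus.vocabulary)}"
        )
    kept = np.arange(keep)
    if min_doc_frequency > 0:
        kept = kept[corpus.vocabulary.doc_frequency[kept] >= min_doc_frequency]
    kept_set = set(int(i) for i in kept)
    doc_ids: list[str] = []
    term_lists: list[list[str]] = []
    dropped = 0
    for doc_id, idx in zip(corpus.doc_ids, corpus.documents):
        terms = [corpus.vocabulary.terms[j] for j in idx if int(j) in kept_set]
        if terms:
            doc_ids.append(doc_id)
            term_lists.append(terms)
        else:
            dropped += 1
    return Corpus.from_term_lists(doc_ids, term_lists), dropped


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary statistics of terms-per-document (SD is the population SD)."""
    if corpus.n_docs == 0:
        raise ValueError("empty corpus")
    lens = np.fromiter(
        (len(d) for d in corpus.documents), dtype=np.int64, count=corpus.n_docs
    )
    return CorpusStats(
        n_docs=corpus.n_docs,
        n_terms=corpus.n_terms,
        mean_terms=float(np.mean(lens)),
        median_terms=float(np.median(lens)),
        sd_terms=float(np.std(lens)),
        min_terms=int(lens.min()),
        max_terms=int(lens.max()),
    )
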