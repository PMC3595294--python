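"""Data-partitioned batch self-organizing map over sparse binary documents.

The model is a hexagonal lattice of neurons, each holding a dense reference
vector ``w_i`` over the vocabulary.  Training is the batch SOM variant:

1. Freeze the map.  For each training vector ``x_j`` (a binary document),
   find the best-matching unit (BMU) by cosine similarity.  Because documents
   are sparse binary sets, the cosine reduces to
   ``sum_{k in doc} w_ik / (sqrt(|doc|) * ||w_i||)``.
2. For every neuron ``i``, add to its accumulators a Gaussian-kernel-weighted
   share of the document: ``numerator_i += h(d(b, i)) * x_j`` and
   ``denominator_i += h(d(b, i))``, where ``b`` is the BMU,
   ``h(d) = exp(-d^2 / (2 sigma^2))`` and ``d`` is lattice grid distance.
   The kernel is evaluated through a per-batch lookup table over quantized
   distances.
3. At the end of the batch, every neuron with positive denominator is set to
   ``numerator_i / denominator_i`` (a convex combination of binary inputs, so
   weights stay in [0, 1] forever), sigma steps down, and the accumulators
   reset to zero.

Accumulation is additive, so a batch may be split into partitions whose
accumulators are merged in fixed order before the map update -- the serial
and partitioned runs agree to floating-point summation tolerance.  The sigma
schedule decays linearly across batches from ``sigma_start`` (default:
``max(rows, cols)``, i.e. roughly the size of the map) down to ``sigma_end``
(default 1); a ``sigma_within_batch`` flag instead restarts the decay inside
every batch, for comparison.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus import Corpus, TermVocabulary
from .lattice import HexLattice

__all__ = [
    "SOMModel",
    "TrainingSchedule",
    "AccumulatorSet",
    "KernelTable",
    "init_model",
    "cosine_bmu",
    "bmu_batch",
    "build_kernel_table",
    "accumulate",
    "merge_accumulators",
    "finalize_batch",
    "train",
    "save_model",
    "load_model",
]

#: kernel weights below this floor are treated as exactly zero
KERNEL_FLOOR = 1e-9
#: grid-distance quantization step of the kernel lookup table
KERNEL_STEP = 0.01

FORMAT_VERSION = 1


@dataclass
class SOMModel:
    lattice: HexLattice
    vocabulary: TermVocabulary
    weights: np.ndarray  # (n_neurons, n_terms) float64 in [0, 1]
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = (self.lattice.n_neurons, len(self.vocabulary))
        if self.weights.shape != expect:
            raise ValueError(
                f"weight shape {self.weights.shape} != lattice x vocabulary {expect}"
            )

    def weight_norms(self) -> np.ndarray:
        return np.linalg.norm(self.weights, axis=1)


@dataclass(frozen=True)
class TrainingSchedule:
    n_batches: int
    steps_per_batch: int
    sigma_start: float | None = None  # None -> max(rows, cols)
    sigma_end: float = 1.0
    partitions: int = 1
    seed: int = 0
    sigma_within_batch: bool = False

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.steps_per_batch < 1:
            raise ValueError("steps_per_batch must be >= 1")
        if self.partitions < 1:
            raise ValueError("partitions must be >= 1")
        if self.sigma_end <= 0:
            raise ValueError("sigma_end must be > 0")
        if self.sigma_start is not None and self.sigma_start < self.sigma_end:
            raise ValueError("need sigma_start >= sigma_end")

    def sigma_at(self, batch: int, n_batches: int, start: float) -> float:
        if n_batches == 1:
            return start
        frac = batch / (n_batches - 1)
        return start + (self.sigma_end - start) * frac


@dataclass
class AccumulatorSet:
    """Pending kernel-weighted updates for one batch (or one partition)."""

    numerator: np.ndarray  # (n_neurons, n_terms)
    denominator: np.ndarray  # (n_neurons,)

    @classmethod
    def zeros(cls, n_neurons: int, n_terms: int) -> "AccumulatorSet":
        return cls(
            numerator=np.zeros((n_neurons, n_terms)),
            denominator=np.zeros(n_neurons),
        )

    def reset(self) -> None:
        self.numerator[:] = 0.0
        self.denominator[:] = 0.0


class KernelTable:
    """Gaussian neighborhood kernel as a lookup over quantized distances.

    ``h(d) = exp(-d^2 / (2 sigma^2))``, tabulated at multiples of
    ``KERNEL_STEP`` up to ``max_distance``; entries below ``KERNEL_FLOOR``
    are zero, which truncates the effective kernel radius.
    """

    def __init__(self, sigma: float, max_distance: float):
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.sigma = float(sigma)
        self.max_distance = float(max_distance)
        # +2 headroom so any rounded distance <= max_distance stays in range
        n = int(np.ceil(self.max_distance / KERNEL_STEP)) + 2
        d = np.arange(n) * KERNEL_STEP
        v = np.exp(-(d**2) / (2.0 * self.sigma**2))
        v[v < KERNEL_FLOOR] = 0.0
        self.values = v

    def lookup(self, distances: np.ndarray) -> np.ndarray:
        """Kernel weights for an array of grid distances (vectorized)."""
        idx = np.rint(np.asarray(distances) / KERNEL_STEP).astype(np.int64)
        out = np.zeros(idx.shape)
        ok = idx < len(self.values)
        out[ok] = self.values[idx[ok]]
        return out


def build_kernel_table(sigma: float, max_distance: float) -> KernelTable:
    return KernelTable(sigma, max_distance)


def init_model(
    lattice: HexLattice, vocabulary: TermVocabulary, seed: int
) -> SOMModel:
    """Random {0, 1} initialization: each weight is 0 or 1 with probability 1/2."""
    rng = np.random.default_rng(seed)
    w = rng.integers(0, 2, size=(lattice.n_neurons, len(vocabulary))).astype(
        np.float64
    )
    return SOMModel(lattice=lattice, vocabulary=vocabulary, weights=w)


def _doc_array(doc) -> np.ndarray:
    idx = np.asarray(doc, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("document has no terms")
    return idx


def cosine_bmu(model: SOMModel, doc) -> int:
    """Best-matching unit of a sparse binary document by cosine similarity.

    Ties break to the lowest linear index; zero-norm neurons score 0.
    """
    idx = _doc_array(doc)
    norms = model.weight_norms()
    dots = model.weights[:, idx].sum(axis=1)
    sims = np.zeros(model.lattice.n_neurons)
    ok = norms > 0
    sims[ok] = dots[ok] / (norms[ok] * np.sqrt(len(idx)))
    return int(np.argmax(sims))


def bmu_batch(
    weights: np.ndarray, norms: np.ndarray, docs: sp.csr_matrix
) -> tuple[np.ndarray, np.ndarray]:
    """BMU index and similarity for every row of a binary document matrix."""
    lens = np.asarray(docs.sum(axis=1)).ravel()
    sims = docs @ weights.T  # (docs, neurons)
    denom = np.where(norms > 0, norms, 1.0)
    sims = sims / denom[None, :]
    sims[:, norms == 0] = 0.0
    sims /= np.sqrt(lens)[:, None]
    bmus = np.argmax(sims, axis=1)
    return bmus, sims[np.arange(sims.shape[0]), bmus]


def accumulate(
    acc: AccumulatorSet, model: SOMModel, doc, kernel: KernelTable
) -> AccumulatorSet:
    """Accumulate one document: kernel-weighted around its BMU (in place)."""
    idx = _doc_array(doc)
    b = cosine_bmu(model, idx)
    h = kernel.lookup(model.lattice.distances_from(b))
    nz = np.nonzero(h)[0]
    acc.numerator[np.ix_(nz, idx)] += h[nz][:, None]
    acc.denominator[nz] += h[nz]
    return acc


def merge_accumulators(parts: list[AccumulatorSet]) -> AccumulatorSet:
    """Elementwise sum of partition accumulators, in partition order."""
    if not parts:
        raise ValueError("no accumulators to merge")
    shape = parts[0].numerator.shape
    for p in parts:
        if p.numerator.shape != shape or p.denominator.shape != (shape[0],):
            raise ValueError("accumulator shape mismatch")
    out = AccumulatorSet.zeros(*shape)
    for p in parts:
        out.numerator += p.numerator
        out.denominator += p.denominator
    return out


def finalize_batch(model: SOMModel, acc: AccumulatorSet) -> SOMModel:
    """Apply the batch update and reset the accumulators.

    Neurons with zero denominator (never reached by any kernel) keep their
    previous reference vector, which preserves the [0, 1] weight invariant.
    """
    updated = acc.denominator > 0
    # the exact ratio is a convex combination of binary inputs, so it lies in
    # [0, 1]; clip away floating-point summation-order epsilon
    model.weights[updated] = np.clip(
        acc.numerator[updated] / acc.denominator[updated][:, None], 0.0, 1.0
    )
    acc.reset()
    return model


def _accumulate_partition(
    weights: np.ndarray,
    norms: np.ndarray,
    lattice: HexLattice,
    docs: sp.csr_matrix,
    kernel: KernelTable,
) -> tuple[AccumulatorSet, float]:
    """Vectorized accumulation of one partition under a frozen map.

    Equivalent to repeated :func:`accumulate`: documents are grouped by BMU,
    per-BMU binary sums are spread through the kernel with one matrix product.
    Returns the partition accumulators and the summed BMU similarity.
    """
    n, V = weights.shape
    acc = AccumulatorSet.zeros(n, V)
    if docs.shape[0] == 0:
        return acc, 0.0
    bmus, sims = bmu_batch(weights, norms, docs)
    uniq, inverse, counts = np.unique(bmus, return_inverse=True, return_counts=True)
    # per-unique-BMU sums of the binary document vectors
    group = sp.csr_matrix(
        (np.ones(docs.shape[0]), (inverse, np.arange(docs.shape[0]))),
        shape=(len(uniq), docs.shape[0]),
    )
    sums = group @ docs  # (n_uniq, V) sparse
    K = np.empty((len(uniq), n))
    for j, b in enumerate(uniq):
        K[j] = kernel.lookup(lattice.distances_from(int(b)))
    acc.numerator += K.T @ sums
    acc.denominator += K.T @ counts
    return acc, float(sims.sum())


def train(
    corpus: Corpus, lattice: HexLattice, schedule: TrainingSchedule
) -> SOMModel:
    """Run the data-partitioned batch SOM over a corpus.

    Each batch presents a rotating contiguous window of ``steps_per_batch``
    documents (wrapping around the corpus, so the full corpus is cycled every
    ``ceil(n_docs / steps_per_batch)`` batches); the window is split into
    ``partitions`` contiguous chunks whose accumulators are merged in
    partition order.  Deterministic for a fixed seed and schedule, and
    partition-count invariant up to floating-point summation order.
    """
    if corpus.n_docs == 0:
        raise ValueError("empty corpus")
    start = (
        float(schedule.sigma_start)
        if schedule.sigma_start is not None
        else float(max(lattice.rows, lattice.cols))
    )
    model = init_model(lattice, corpus.vocabulary, schedule.seed)
    X = corpus.occurrence_matrix()
    max_d = float(
        np.hypot(
            lattice.cols - 1 + 0.5, (lattice.rows - 1) * np.sqrt(3) / 2
        )
    )
    n_docs = corpus.n_docs
    s = schedule.steps_per_batch

    for b in range(schedule.n_batches):
        window = np.arange(b * s, (b + 1) * s) % n_docs
        chunks = np.array_split(window, schedule.partitions)
        if schedule.sigma_within_batch:
            # literal per-batch reading: sigma decays from start to end
            # across the partitions of every batch
            sigmas = [
                schedule.sigma_at(p, max(schedule.partitions, 2), start)
                for p in range(schedule.partitions)
            ]
        else:
            sigma_b = schedule.sigma_at(b, schedule.n_batches, start)
            sigmas = [sigma_b] * schedule.partitions
        norms = model.weight_norms()
        parts = []
        sim_sum = 0.0
        for chunk, sigma_p in zip(chunks, sigmas):
            kernel = build_kernel_table(sigma_p, max_d)
            part, ssum = _accumulate_partition(
                model.weights, norms, lattice, X[chunk], kernel
            )
            parts.append(part)
            sim_sum += ssum
        acc = merge_accumulators(parts)
        model = finalize_batch(model, acc)
        mean_sim = sim_sum / len(window)
        model.training_log.append(
            {
                "batch": b,
                "sigma": sigmas[0] if not schedule.sigma_within_batch else sigmas,
                "steps": int(len(window)),
                "mean_bmu_similarity": mean_sim,
                "quantization_error": 1.0 - mean_sim,
            }
        )
    return model


def save_model(model: SOMModel, path: str, schedule: TrainingSchedule | None = None) -> None:
    """Persist a model directory: metadata.json, weights.mtx, vocabulary.txt."""
    os.makedirs(path, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "lattice": model.lattice.metadata(),
        "vocabulary_sha1": model.vocabulary.sha1(),
        "n_terms": len(model.vocabulary),
        "training_log": model.training_log,
    }
    if schedule is not None:
        meta["schedule"] = {
            "n_batches": schedule.n_batches,
            "steps_per_batch": schedule.steps_per_batch,
            "sigma_start": schedule.sigma_start,
            "sigma_end": schedule.sigma_end,
            "partitions": schedule.partitions,
            "seed": schedule.seed,
            "sigma_within_batch": schedule.sigma_within_batch,
        }
    with open(os.path.join(path, "metadata.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    scipy.io.mmwrite(os.path.join(path, "weights.mtx"), model.weights)
    with open(os.path.join(path, "vocabulary.txt"), "w", encoding="utf-8") as fh:
        for t, f in zip(model.vocabulary.terms, model.vocabulary.doc_frequency):
            fh.write(f"{t}\t{int(f)}\n")


def load_model(path: str) -> SOMModel:
    meta_path = os.path.join(path, "metadata.json")
    if not os.path.isdir(path) or not os.path.exists(meta_path):
        raise FileNotFoundError(f"not a model directory: {path}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    lattice = HexLattice.from_metadata(meta["lattice"])
    terms, freqs = [], []
    with open(os.path.join(path, "vocabulary.txt"), encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            t, f = line.split("\t")
            terms.append(t)
            freqs.append(int(f))
    vocab = TermVocabulary(tuple(terms), np.array(freqs, dtype=np.int64))
    weights = np.asarray(scipy.io.mmread(os.path.join(path, "weights.mtx")))
    model = SOMModel(lattice=lattice, vocabulary=vocab, weights=weights)
    model.training_log = meta.get("training_log", [])
    return model
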