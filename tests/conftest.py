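import numpy as np
import pytest

from meshsom import (
    HexLattice,
    SyntheticSpec,
    TrainingSchedule,
    dominance_matrix,
    generate_corpus,
    train,
)
from meshsom.corpus import TermVocabulary
from meshsom.dominance import DominanceRanking


@pytest.fixture(scope="session")
def topic_corpus():
    """3-topic synthetic corpus with cleanly resolvable latent structure."""
    spec = SyntheticSpec(
        n_docs=1500, vocab_size=200, n_topics=3, topic_vocab_overlap=0.05,
        seed=7,
    )
    corpus, truth = generate_corpus(spec)
    return corpus, truth


@pytest.fixture(scope="session")
def trained_model(topic_corpus):
    """Small trained SOM shared across test modules (15x15, 30 batches)."""
    corpus, _ = topic_corpus
    schedule = TrainingSchedule(
        n_batches=30, steps_per_batch=corpus.n_docs, partitions=1, seed=7
    )
    return train(corpus, HexLattice(15, 15), schedule)


@pytest.fixture(scope="session")
def trained_ranking(trained_model):
    return dominance_matrix(trained_model)


def ranking_from_labels(labels: np.ndarray, n_terms: int) -> DominanceRanking:
    """Build a synthetic one-hot DominanceRanking from a per-neuron label array.

    Convenience for clustering/placement tests that need a ranking with known
    rank-1 terms without training a model.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    n = len(labels)
    dom = np.zeros((n, n_terms))
    dom[np.arange(n), labels] = 1.0
    ranked = np.argsort(-dom, axis=1, kind="stable")[:, : min(10, n_terms)]
    vocab = TermVocabulary(
        tuple(f"t{i:03d}" for i in range(n_terms)),
        np.zeros(n_terms, dtype=np.int64),
    )
    return DominanceRanking(
        vocabulary=vocab,
        dominance=dom,
        ranked_terms=ranked,
        degenerate=np.zeros(n, dtype=bool),
        max_rank_materialized=ranked.shape[1],
    )
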