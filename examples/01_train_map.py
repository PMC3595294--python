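"""Generate a synthetic term-document corpus and train a batch SOM on it.

Builds a 10-topic MeSH-like corpus (sparse binary documents, ~7 terms each,
plus a small stratum of cross-topic procedural terms), trains a 20x20
hexagonal map, and prints the convergence diagnostics.
"""

from meshsom import (
    HexLattice,
    SyntheticSpec,
    TrainingSchedule,
    corpus_stats,
    generate_corpus,
    train,
)

spec = SyntheticSpec(n_docs=2000, seed=13)
corpus, truth = generate_corpus(spec)
st = corpus_stats(corpus)
print(f"corpus: {st.n_docs} docs, {st.n_terms} terms, "
      f"terms/doc mean {st.mean_terms:.2f} (sd {st.sd_terms:.2f})")

schedule = TrainingSchedule(n_batches=25, steps_per_batch=2000, seed=13)
model = train(corpus, HexLattice(20, 20), schedule)

first, last = model.training_log[0], model.training_log[-1]
print(f"sigma schedule: {first['sigma']:.1f} -> {last['sigma']:.1f} "
      f"over {len(model.training_log)} batches")
print(f"quantization error: {first['quantization_error']:.3f} -> "
      f"{last['quantization_error']:.3f}")
print("(falling quantization error = documents sit closer to their "
      "best-matching neurons as the map organizes)")
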