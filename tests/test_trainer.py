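import numpy as np
import pytest

from meshsom import (
    AccumulatorSet,
    Corpus,
    HexLattice,
    SyntheticSpec,
    TrainingSchedule,
    accumulate,
    build_kernel_table,
    cosine_bmu,
    finalize_batch,
    generate_corpus,
    init_model,
    load_model,
    merge_accumulators,
    save_model,
    train,
)
from meshsom.corpus import TermVocabulary
from meshsom.trainer import KERNEL_FLOOR, KERNEL_STEP, SOMModel


def _vocab(n):
    return TermVocabulary(
        tuple(f"t{i:03d}" for i in range(n)), np.zeros(n, dtype=np.int64)
    )


def _model(weights, rows, cols):
    weights = np.asarray(weights, dtype=np.float64)
    return SOMModel(
        lattice=HexLattice(rows, cols),
        vocabulary=_vocab(weights.shape[1]),
        weights=weights,
    )


def _random_docs(rng, n_docs, n_terms, max_len=6):
    return [
        np.sort(rng.choice(n_terms, size=rng.integers(1, max_len + 1), replace=False))
        for _ in range(n_docs)
    ]


class TestInit:
    def test_deterministic_per_seed(self):
        lat, v = HexLattice(6, 6), _vocab(20)
        a = init_model(lat, v, seed=3)
        b = init_model(lat, v, seed=3)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_binary_and_balanced(self):
        m = init_model(HexLattice(30, 30), _vocab(100), seed=1)
        assert set(np.unique(m.weights)) <= {0.0, 1.0}
        frac = m.weights.mean()
        assert 0.47 <= frac <= 0.53  # binomial bound at 90,000 draws


class TestCosineBmu:
    def test_closed_form_example(self):
        m = _model([[1, 1, 0], [0, 0, 1]], 1, 2)
        assert cosine_bmu(m, [0, 1]) == 0  # similarity 1 vs 0

    def test_tie_breaks_to_lowest_index(self):
        m = _model(np.ones((4, 3)), 2, 2)
        assert cosine_bmu(m, [0]) == 0

    def test_empty_document_errors(self):
        m = _model(np.ones((4, 3)), 2, 2)
        with pytest.raises(ValueError):
            cosine_bmu(m, [])

    def test_zero_norm_neurons_score_zero(self):
        m = _model([[0, 0, 0], [0, 1, 0]], 1, 2)
        assert cosine_bmu(m, [1]) == 1

    def test_matches_dense_oracle(self):
        """Sparse-path BMU equals brute-force dense cosine on random models."""
        rng = np.random.default_rng(0)
        w = rng.random((50, 20))
        m = _model(w, 5, 10)
        for doc in _random_docs(rng, 200, 20):
            x = np.zeros(20)
            x[doc] = 1.0
            sims = w @ x / (np.linalg.norm(w, axis=1) * np.linalg.norm(x))
            assert cosine_bmu(m, doc) == int(np.argmax(sims))


class TestKernelTable:
    def test_h0_is_one(self):
        assert build_kernel_table(2.0, 10.0).lookup(np.array([0.0]))[0] == 1.0

    def test_unit_distance_closed_form(self):
        t = build_kernel_table(1.0, 10.0)
        assert t.lookup(np.array([1.0]))[0] == pytest.approx(np.exp(-0.5))

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            build_kernel_table(0.0, 10.0)

    def test_strictly_decreasing_until_floor(self):
        v = build_kernel_table(1.5, 20.0).values
        nz = v[v > 0]
        assert np.all(np.diff(nz) < 0)

    def test_lookup_matches_direct_evaluation(self):
        """Table lookup agrees with exp(-d^2/2s^2) to quantization error."""
        rng = np.random.default_rng(1)
        sigma = 3.0
        t = build_kernel_table(sigma, 30.0)
        d = rng.uniform(0, 29.9, size=1000)
        got = t.lookup(d)
        dq = np.rint(d / KERNEL_STEP) * KERNEL_STEP
        want = np.exp(-(dq**2) / (2 * sigma**2))
        want[want < KERNEL_FLOOR] = 0.0
        assert np.allclose(got, want, rtol=0, atol=1e-15)


class TestAccumulate:
    def test_tiny_sigma_updates_only_bmu_row(self):
        rng = np.random.default_rng(2)
        w = rng.random((9, 5))
        m = _model(w, 3, 3)
        acc = AccumulatorSet.zeros(9, 5)
        kernel = build_kernel_table(1e-3, 10.0)  # collapses to BMU indicator
        doc = np.array([1, 3])
        b = cosine_bmu(m, doc)
        accumulate(acc, m, doc, kernel)
        expected_num = np.zeros((9, 5))
        expected_num[b, [1, 3]] = 1.0
        assert np.array_equal(acc.numerator, expected_num)
        assert acc.denominator[b] == 1.0 and acc.denominator.sum() == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.random((9, 6))
        kernel = build_kernel_table(1.5, 10.0)
        d1, d2 = np.array([0, 2]), np.array([3, 4, 5])
        a = AccumulatorSet.zeros(9, 6)
        accumulate(a, _model(w, 3, 3), d1, kernel)
        accumulate(a, _model(w, 3, 3), d2, kernel)
        b = AccumulatorSet.zeros(9, 6)
        accumulate(b, _model(w, 3, 3), d2, kernel)
        accumulate(b, _model(w, 3, 3), d1, kernel)
        assert np.allclose(a.numerator, b.numerator, atol=1e-15)
        assert np.allclose(a.denominator, b.denominator, atol=1e-15)

    def test_matches_naive_oracle_over_batch(self):
        """Accumulators over 100 docs equal the closed-form kernel-weighted
        sums computed by a naive O(docs x neurons x terms) loop."""
        rng = np.random.default_rng(4)
        rows, cols, V = 5, 10, 12
        w = rng.random((rows * cols, V))
        m = _model(w, rows, cols)
        sigma = 2.0
        kernel = build_kernel_table(sigma, 30.0)
        docs = _random_docs(rng, 100, V)
        acc = AccumulatorSet.zeros(rows * cols, V)
        for doc in docs:
            accumulate(acc, m, doc, kernel)
        # independent closed form (same quantized kernel definition)
        lat = m.lattice
        num = np.zeros((rows * cols, V))
        den = np.zeros(rows * cols)
        for doc in docs:
            x = np.zeros(V)
            x[doc] = 1.0
            sims = w @ x / (np.linalg.norm(w, axis=1) * np.linalg.norm(x))
            b = int(np.argmax(sims))
            for i in range(rows * cols):
                dq = round(lat.grid_distance(b, i) / KERNEL_STEP) * KERNEL_STEP
                h = np.exp(-(dq**2) / (2 * sigma**2))
                if h < KERNEL_FLOOR:
                    h = 0.0
                num[i] += h * x
                den[i] += h
        assert np.allclose(acc.numerator, num, atol=1e-9)
        assert np.allclose(acc.denominator, den, atol=1e-9)


class TestMergeFinalize:
    def test_merge_identity_and_zero(self):
        a = AccumulatorSet(np.arange(6.0).reshape(2, 3), np.array([1.0, 2.0]))
        merged = merge_accumulators([a])
        assert np.array_equal(merged.numerator, a.numerator)
        z = AccumulatorSet.zeros(2, 3)
        merged2 = merge_accumulators([a, z])
        assert np.array_equal(merged2.numerator, a.numerator)
        assert np.array_equal(merged2.denominator, a.denominator)

    def test_merge_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            merge_accumulators(
                [AccumulatorSet.zeros(2, 3), AccumulatorSet.zeros(3, 3)]
            )

    def test_four_way_split_equals_unpartitioned(self):
        rng = np.random.default_rng(5)
        w = rng.random((16, 8))
        kernel = build_kernel_table(1.2, 10.0)
        docs = _random_docs(rng, 40, 8)
        whole = AccumulatorSet.zeros(16, 8)
        for d in docs:
            accumulate(whole, _model(w, 4, 4), d, kernel)
        parts = []
        for chunk in np.array_split(np.arange(40), 4):
            p = AccumulatorSet.zeros(16, 8)
            for k in chunk:
                accumulate(p, _model(w, 4, 4), docs[k], kernel)
            parts.append(p)
        merged = merge_accumulators(parts)
        assert np.allclose(merged.numerator, whole.numerator, rtol=1e-9)
        assert np.allclose(merged.denominator, whole.denominator, rtol=1e-9)

    def test_finalize_divides_and_preserves_orphans(self):
        m = _model([[0.2, 0.9, 0.4], [0.5, 0.5, 0.5]], 1, 2)
        acc = AccumulatorSet(
            np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0]]), np.array([2.0, 0.0])
        )
        finalize_batch(m, acc)
        assert np.allclose(m.weights[0], [1.0, 0.5, 0.0])
        assert np.allclose(m.weights[1], [0.5, 0.5, 0.5])  # orphan unchanged
        assert acc.denominator.sum() == 0.0  # reset

    def test_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(6)
        m = init_model(HexLattice(4, 4), _vocab(10), seed=6)
        kernel = build_kernel_table(2.0, 10.0)
        for _ in range(3):
            acc = AccumulatorSet.zeros(16, 10)
            for d in _random_docs(rng, 30, 10):
                accumulate(acc, m, d, kernel)
            finalize_batch(m, acc)
        assert m.weights.min() >= 0.0 and m.weights.max() <= 1.0


class TestTrain:
    def test_empty_corpus_errors(self):
        c = Corpus.from_term_lists([], [])
        with pytest.raises(ValueError):
            train(c, HexLattice(3, 3), TrainingSchedule(1, 1))

    def test_huge_sigma_single_batch_flattens_map(self):
        """With sigma >> map size every neuron averages all documents, so all
        rows converge to the corpus mean vector."""
        corpus, _ = generate_corpus(
            SyntheticSpec(n_docs=200, vocab_size=50, n_topics=2, seed=1)
        )
        model = train(
            corpus,
            HexLattice(4, 4),
            TrainingSchedule(
                n_batches=1, steps_per_batch=200, sigma_start=1e4, seed=1
            ),
        )
        spread = np.abs(model.weights - model.weights[0]).max()
        assert spread < 1e-6
        mean_vec = np.asarray(
            corpus.occurrence_matrix().mean(axis=0)
        ).ravel()
        assert np.allclose(model.weights[0], mean_vec, atol=1e-6)

    def test_sigma_zero_limit_is_kmeans_step(self):
        """A one-batch update at tiny sigma equals the per-BMU document mean."""
        corpus, _ = generate_corpus(
            SyntheticSpec(n_docs=150, vocab_size=40, n_topics=2, seed=2)
        )
        lat = HexLattice(4, 4)
        sched = TrainingSchedule(
            n_batches=1, steps_per_batch=150, sigma_start=1e-3, sigma_end=1e-3, seed=2
        )
        model = train(corpus, lat, sched)
        init = init_model(lat, corpus.vocabulary, seed=2)
        X = corpus.occurrence_matrix().toarray()
        bmus = np.array([cosine_bmu(init, d) for d in corpus.documents])
        for i in range(16):
            mine = X[bmus == i]
            if len(mine):
                assert np.allclose(model.weights[i], mine.mean(axis=0), atol=1e-9)
            else:
                assert np.array_equal(model.weights[i], init.weights[i])

    def test_partition_count_does_not_change_result(self):
        corpus, _ = generate_corpus(
            SyntheticSpec(n_docs=400, vocab_size=80, n_topics=3, seed=3)
        )
        lat = HexLattice(8, 8)
        kw = dict(n_batches=8, steps_per_batch=400, seed=3)
        m1 = train(corpus, lat, TrainingSchedule(partitions=1, **kw))
        m3 = train(corpus, lat, TrainingSchedule(partitions=3, **kw))
        assert np.allclose(m1.weights, m3.weights, rtol=1e-7, atol=1e-12)

    def test_quantization_error_trend_last_quartile(self, trained_model):
        """QE is non-increasing over the last quartile of batches (with slack)."""
        qe = [b["quantization_error"] for b in trained_model.training_log]
        tail = qe[3 * len(qe) // 4 :]
        assert tail[-1] <= tail[0] + 0.01

    def test_training_log_records_sigma_and_steps(self, trained_model):
        log = trained_model.training_log
        assert len(log) == 30
        sigmas = [b["sigma"] for b in log]
        assert sigmas[0] == 15.0 and sigmas[-1] == 1.0
        assert all(s["steps"] == 1500 for s in log)


class TestPersistence:
    def test_round_trip(self, tmp_path, trained_model):
        d = str(tmp_path / "model")
        save_model(trained_model, d)
        back = load_model(d)
        assert np.allclose(back.weights, trained_model.weights, atol=0)
        assert back.vocabulary.terms == trained_model.vocabulary.terms
        assert back.lattice.metadata() == trained_model.lattice.metadata()

    def test_missing_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(str(tmp_path / "nope"))
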