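import numpy as np
import pytest
from scipy.special import expit

from ppisign import (
    FeatureVocabulary,
    InstancePair,
    Pair,
    decision_values,
    fit_codec,
    load_model,
    pool_instances,
    predict_pair,
    save_model,
    train,
)
from ppisign.multilabel import CombinedLabelCodec, _primal_objective_grad

ACT, INH, OTH = "activation", "inhibition", "others"


def bisect_stationary_weight(C, lo=0.0, hi=50.0, iters=200):
    """Root of w - 2C*sigmoid(-w) = 0: the optimum of the symmetric 1-D
    two-point problem, independent of the trained solver."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid - 2 * C * expit(-mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def random_problem(rng, n=None, d=None):
    n = n or int(rng.integers(4, 30))
    d = d or int(rng.integers(1, 6))
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, size=n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    return X, y


class TestCodec:
    def test_distinct_combination_count(self):
        codec = fit_codec([{ACT}, {INH}, {ACT, INH}, {OTH}, {ACT}])
        assert codec.n_classes == 4

    def test_round_trip(self):
        codec = fit_codec([{ACT}, {ACT, INH}, {OTH}])
        for s in ({ACT}, {ACT, INH}, {OTH}):
            assert codec.decode(codec.encode(s)) == frozenset(s)

    def test_unseen_combination_rejected(self):
        codec = fit_codec([{ACT}, {INH}])
        with pytest.raises(ValueError, match="never observed"):
            codec.encode({ACT, OTH})

    def test_empty_label_set_fatal(self):
        with pytest.raises(ValueError, match="empty label set"):
            fit_codec([{ACT}, set()])

    def test_deterministic_ordering(self):
        c1 = fit_codec([{OTH}, {ACT}, {INH}])
        c2 = fit_codec([{INH}, {OTH}, {ACT}])
        assert c1.combos == c2.combos


class TestTrain:
    def test_matches_1d_stationarity_oracle(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([0, 1])
        model = train(X, y, C=1.0, tol=1e-6, fit_intercept=False)
        expected = bisect_stationary_weight(C=1.0)
        assert model.W[0, 0] == pytest.approx(expected, abs=1e-4)
        assert model.W[0, 0] == pytest.approx(0.675, abs=1e-3)

    def test_weight_vanishes_as_C_shrinks(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([0, 1])
        model = train(X, y, C=1e-6, fit_intercept=False)
        assert abs(model.W[0, 0]) < 1e-4

    def test_objective_bounded_by_zero_vector_value(self, rng):
        for _ in range(10):
            X, y = random_problem(rng)
            C = float(rng.uniform(0.1, 5.0))
            model = train(X, y, C=C)
            bound = C * len(y) * np.log(2.0)
            assert all(obj <= bound + 1e-9 for obj in model.objectives)

    def test_gradient_norm_below_tolerance(self, rng):
        tol = 1e-5
        for _ in range(10):
            X, y = random_problem(rng)
            model = train(X, y, C=1.0, tol=tol)
            assert model.converged
            for k in range(model.n_classes):
                yk = np.where(y == k, 1.0, -1.0)
                wb = np.concatenate([model.W[k], [model.b[k]]])
                _, g = _primal_objective_grad(wb, X.astype(float), yk, 1.0, True)
                assert np.max(np.abs(g)) <= tol * (1 + 1e-9)

    def test_weight_norm_nondecreasing_in_C(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3)) + np.array([2.0, 0, 0])
        X[10:] -= np.array([4.0, 0, 0])  # linearly separable on feature 0
        y = np.array([0] * 10 + [1] * 10)
        norms = []
        for C in (0.01, 0.1, 1.0, 10.0):
            model = train(X, y, C=C, tol=1e-8)
            norms.append(np.linalg.norm(model.W[0]))
        assert all(a <= b + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_instance_order_does_not_matter(self, rng):
        X, y = random_problem(rng, n=40, d=4)
        perm = rng.permutation(len(y))
        m1 = train(X, y, tol=1e-8)
        m2 = train(X[perm], y[perm], tol=1e-8)
        np.testing.assert_allclose(m1.W, m2.W, atol=1e-5)
        np.testing.assert_allclose(m1.b, m2.b, atol=1e-5)

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="single class"):
            train(np.ones((3, 2)), np.zeros(3, dtype=int))

    def test_nonpositive_C_fatal(self):
        X = np.array([[1.0], [-1.0]])
        with pytest.raises(ValueError, match="C must be"):
            train(X, np.array([0, 1]), C=0.0)

    def test_agrees_with_reference_implementation(self, rng):
        """Dual-route check: our primal solver vs scikit-learn's logistic
        regression (same objective, unpenalized intercept) on binary data."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = random_problem(rng, n=60, d=5)
        C = 0.7
        mine = train(X, y, C=C, tol=1e-8)
        ref = sklearn.LogisticRegression(C=C, tol=1e-10, max_iter=5000).fit(X, y)
        # our class-1 one-vs-rest scorer should match sklearn's binary scorer
        np.testing.assert_allclose(mine.W[1], ref.coef_[0], atol=1e-4)
        np.testing.assert_allclose(mine.b[1], ref.intercept_[0], atol=1e-4)


class TestDecisionValues:
    def _toy_model(self):
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        y = np.array([0, 1, 0, 1])
        return train(X, y)

    def test_zero_vector_scores_equal_biases(self):
        model = self._toy_model()
        np.testing.assert_allclose(
            decision_values(model, np.zeros(2)), model.b
        )

    def test_hand_set_weights_dot_product(self):
        model = self._toy_model()
        model.W = np.array([[1.0, 0.0], [0.0, 0.0]])
        model.b = np.zeros(2)
        scores = decision_values(model, np.array([2.0, 1.0]))
        assert scores[0] == pytest.approx(2.0)

    def test_length_mismatch_fatal(self):
        model = self._toy_model()
        with pytest.raises(ValueError, match="does not match"):
            decision_values(model, np.zeros(5))


class TestPredictPair:
    def _model(self, W, b, combos):
        W = np.asarray(W, dtype=float)
        vocab = FeatureVocabulary(terms=tuple(f"g{i}" for i in range(W.shape[1])))
        model = train(
            np.eye(W.shape[1]),
            np.arange(W.shape[1]) % W.shape[0],
            codec=CombinedLabelCodec(combos=tuple(map(frozenset, combos))),
            vocab=vocab,
        )
        model.W = W
        model.b = np.asarray(b, dtype=float)
        return model

    def test_larger_decision_value_wins_fusion(self):
        model = self._model(
            W=[[1.0, 0.0], [0.0, 1.0]], b=[0.0, 0.0],
            combos=[{ACT}, {INH}],
        )
        inst = InstancePair(
            pair=Pair.make("A", "B"),
            target_vec=np.array([1.3, 0.0]),   # argmax class 0 (act), max 1.3
            homolog_vec=np.array([0.0, 0.9]),  # argmax class 1 (inh), max 0.9
        )
        rec = predict_pair(model, inst)
        assert rec.target_labels == {ACT}
        assert rec.homolog_labels == {INH}
        assert rec.fused_labels == {ACT}

    def test_single_source_when_target_null(self):
        model = self._model(
            W=[[1.0, 0.0], [0.0, 1.0]], b=[0.0, 0.0],
            combos=[{ACT, INH}, {OTH}],
        )
        inst = InstancePair(
            pair=Pair.make("A", "B"),
            target_vec=None,
            homolog_vec=np.array([2.0, 0.0]),
        )
        rec = predict_pair(model, inst)
        assert rec.target_labels is None
        assert rec.fused_labels == {ACT, INH}

    def test_tie_goes_to_target_instance(self):
        model = self._model(
            W=[[1.0, 0.0], [0.0, 1.0]], b=[0.0, 0.0],
            combos=[{ACT}, {INH}],
        )
        inst = InstancePair(
            pair=Pair.make("A", "B"),
            target_vec=np.array([1.0, 0.0]),
            homolog_vec=np.array([0.0, 1.0]),
        )
        rec = predict_pair(model, inst)
        assert rec.target_max_decision == rec.homolog_max_decision
        assert rec.fused_labels == rec.target_labels == {ACT}

    def test_both_null_flagged_unpredictable(self):
        model = self._model(
            W=[[1.0, 0.0], [0.0, 1.0]], b=[0.0, 0.0], combos=[{ACT}, {INH}],
        )
        inst = InstancePair(pair=Pair.make("A", "B"), target_vec=None, homolog_vec=None)
        rec = predict_pair(model, inst)
        assert rec.unpredictable
        assert rec.fused_labels is None


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = random_problem(rng, n=30, d=4)
        model = train(X, y)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.W, model.W)
        np.testing.assert_allclose(loaded.b, model.b)
        assert loaded.codec.combos == model.codec.combos
        assert loaded.vocab.terms == model.vocab.terms
        assert loaded.vocab_fingerprint == model.vocab_fingerprint

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="unsupported model format"):
            load_model(path)


class TestPoolInstances:
    def test_pooled_rows_and_codes(self):
        vocab = FeatureVocabulary(terms=("g1", "g2"))
        codec = fit_codec([{ACT}, {INH}])
        insts = [
            InstancePair(
                pair=Pair.make("A", "B", {ACT}),
                target_vec=np.array([1, 0], dtype=np.int8),
                homolog_vec=np.array([2, 0], dtype=np.int8),
            ),
            InstancePair(
                pair=Pair.make("C", "D", {INH}),
                target_vec=None,
                homolog_vec=np.array([0, 2], dtype=np.int8),
            ),
        ]
        X, y = pool_instances(insts, codec)
        assert X.shape == (3, 2)  # null target vector excluded
        assert y.tolist() == [codec.encode({ACT})] * 2 + [codec.encode({INH})]
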