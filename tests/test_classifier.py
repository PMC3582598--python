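"""One-vs-rest SVM training, score fusion and the multi-label decision rule.

The independent oracle for the SVM fit is direct minimization of the
primal soft-margin objective 0.5 ||w||^2 + C sum_i max(0, 1 - y_i (w.x_i + b))
with scipy, which shares no code path with the dual solver used by the
implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.metrics.pairwise import pairwise_kernels

from goloc import (
    GOVector,
    KernelSpec,
    MultiLabelSVMModel,
    Prediction,
    QueryVectorSet,
    decide,
    fuse,
    train,
    transform_labels,
)


def primal_svm_oracle(X, y, C):
    """Brute-force linear soft-margin SVM via the primal slack program:
    minimize 0.5 ||w||^2 + C sum_i xi_i subject to xi_i >= 0 and
    xi_i >= 1 - y_i (w.x_i + b), solved as a smooth constrained problem."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    n, d = X.shape

    def objective(theta):
        w, xi = theta[:d], theta[d + 1:]
        return 0.5 * w @ w + C * xi.sum()

    def margin_constraint(theta):
        w, b, xi = theta[:d], theta[d], theta[d + 1:]
        return y * (X @ w + b) - 1.0 + xi

    res = minimize(
        objective, np.zeros(d + 1 + n), method="SLSQP",
        constraints=[{"type": "ineq", "fun": margin_constraint},
                     {"type": "ineq", "fun": lambda t: t[d + 1:]}],
        options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success, res.message
    return res.x[:d], res.x[d]


def random_linear_model(rng, n=12, d=4, M=3):
    X = rng.normal(size=(n, d))
    label_sets = [frozenset({int(rng.integers(1, M + 1))}) for _ in range(n)]
    # guarantee every class has a positive and a negative instance
    for m in range(1, M + 1):
        label_sets[m - 1] = frozenset({m})
    return train(X, label_sets, M, KernelSpec(), C=0.1), X


class TestTransformLabels:
    @pytest.mark.parametrize("labels,M,expected", [
        ({2}, 3, [-1, 1, -1]),
        ({1, 3}, 3, [1, -1, 1]),
        ({1, 2, 3}, 3, [1, 1, 1]),
    ])
    def test_plus_one_iff_member(self, labels, M, expected):
        assert transform_labels(labels, M).tolist() == expected

    def test_empty_or_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_labels(set(), 3)
        with pytest.raises(ValueError):
            transform_labels({4}, 3)


class TestTraining:
    def test_separable_toy_matches_primal_oracle(self):
        """Dual solution agrees with brute-force primal minimization."""
        X = np.array([[2.0, 0.5], [3.0, -0.5], [-2.0, 0.5], [-3.0, -0.2]])
        label_sets = [{1}, {1}, {2}, {2}]
        model = train(X, label_sets, 2, KernelSpec(), C=0.1)
        scores = np.array([model.score_single(x) for x in X])
        assert (np.sign(scores[:, 0]) == [1, 1, -1, -1]).all()
        w_ref, b_ref = primal_svm_oracle(X, [1, 1, -1, -1], 0.1)
        ours = scores[:, 0]
        ref = X @ w_ref + b_ref
        assert np.allclose(ours, ref, atol=1e-3)

    def test_multilabel_protein_is_positive_for_both_classes(self):
        X = np.array([[5.0, 0.0], [0.0, 5.0], [5.0, 5.0], [-5.0, -5.0]])
        label_sets = [{1}, {2}, {1, 2}, {3}]
        model = train(X, label_sets, 3, KernelSpec(), C=0.1)
        scores = model.score_single(np.array([5.0, 5.0]))
        assert scores[0] > 0 and scores[1] > 0

    def test_empty_class_becomes_stub_and_never_predicted(self):
        X = np.array([[1.0, 0.0], [0.9, 0.1], [-1.0, 0.0], [-0.9, -0.1]])
        label_sets = [{1}, {1}, {2}, {2}]
        model = train(X, label_sets, 3, KernelSpec(), C=0.1)
        assert model.class_svms[2].is_stub
        for x in X:
            labels, _ = decide(model.score_single(x))
            assert 3 not in labels

    def test_all_stub_classes_rejected(self):
        X = np.array([[1.0], [2.0], [3.0]])
        with pytest.raises(ValueError):
            train(X, [{1}, {1}, {1}], 2, KernelSpec(), C=0.1)

    def test_kkt_balance_and_box_constraints(self):
        rng = np.random.default_rng(0)
        model, _ = random_linear_model(rng)
        for svm in model.class_svms:
            if svm.is_stub:
                continue
            assert svm.kkt_gap() < 1e-8
            assert (svm.alpha >= -1e-12).all()
            assert (svm.alpha <= model.C + 1e-12).all()

    def test_positive_margin_duplicate_does_not_flip_sign(self):
        """Adding a copy of a confidently-classified point keeps its sign."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(loc=2.0, size=(5, 2)),
                       rng.normal(loc=-2.0, size=(5, 2))])
        label_sets = [{1}] * 5 + [{2}] * 5
        model = train(X, label_sets, 2, KernelSpec(), C=0.1)
        margin_point = X[0]
        assert model.score_single(margin_point)[0] > 0
        X2 = np.vstack([X, margin_point])
        model2 = train(X2, label_sets + [{1}], 2, KernelSpec(), C=0.1)
        assert model2.score_single(margin_point)[0] > 0


class TestScoring:
    def test_dual_equals_weight_form_on_random_models(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            model, X = random_linear_model(rng)
            for x in X:
                assert np.allclose(model.score_single(x),
                                   model.weight_scores(x), atol=1e-9)

    def test_single_key_reduces_to_plain_score(self):
        rng = np.random.default_rng(1)
        model, X = random_linear_model(rng)
        qs = QueryVectorSet((GOVector(np.abs(X[0]), "tf"),), np.array([1.0]))
        assert np.allclose(model.score_query_set(qs),
                           model.score_single(np.abs(X[0])), atol=1e-12)

    def test_linear_fusion_equivalence(self):
        """Fused per-key scores equal the score of the fused vector."""
        rng = np.random.default_rng(7)
        model, _ = random_linear_model(rng)
        for _ in range(20):
            k = int(rng.integers(1, 4))
            vectors = tuple(
                GOVector(rng.integers(0, 5, size=4).astype(float), "tf")
                for _ in range(k))
            weights = rng.random(k) + 0.1
            weights = weights / weights.sum()
            qs = QueryVectorSet(vectors, weights)
            assert np.allclose(model.score_query_set(qs),
                               model.score_single(fuse(qs)), atol=1e-9)

    def test_zero_query_vector_scores_bias_only(self):
        rng = np.random.default_rng(5)
        model, _ = random_linear_model(rng)
        scores = model.score_single(np.zeros(4))
        biases = [svm.bias for svm in model.class_svms]
        assert np.allclose(scores, biases)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        model, _ = random_linear_model(rng)
        with pytest.raises(ValueError):
            model.score_single(np.zeros(7))


class TestKernels:
    @pytest.mark.parametrize("spec,sk_kwargs", [
        (KernelSpec("linear"), {"metric": "linear"}),
        (KernelSpec("rbf", sigma=2.0), {"metric": "rbf", "gamma": 1 / 8.0}),
        (KernelSpec("polynomial", degree=3),
         {"metric": "poly", "degree": 3, "gamma": 1.0, "coef0": 1.0}),
    ])
    def test_gram_matches_reference(self, spec, sk_kwargs):
        rng = np.random.default_rng(9)
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        assert np.allclose(spec.gram(X, Y), pairwise_kernels(X, Y, **sk_kwargs))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf")
        with pytest.raises(ValueError):
            KernelSpec("polynomial", degree=1)
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")

    @pytest.mark.parametrize("spec", [
        KernelSpec("rbf", sigma=0.5), KernelSpec("polynomial", degree=2)])
    def test_nonlinear_training_round_trips_through_json(self, spec, tmp_path):
        rng = np.random.default_rng(11)
        model, X = random_linear_model(rng)
        model_nl = train(X, [{1}] * 4 + [{2}] * 8, 2, spec, C=0.1)
        path = tmp_path / "model.json"
        model_nl.save(path)
        loaded = MultiLabelSVMModel.load(path)
        for x in X:
            assert np.allclose(loaded.score_single(x),
                               model_nl.score_single(x), atol=1e-12)


class TestDecide:
    @pytest.mark.parametrize("scores,expected,fallback", [
        ([0.5, -0.2, 0.1], {1, 3}, False),
        ([-0.3, -0.1, -0.5], {2}, True),
        ([-0.1, -0.1], {1}, True),
    ])
    def test_positive_rule_and_argmax_fallback(self, scores, expected, fallback):
        labels, used = decide(scores)
        assert labels == frozenset(expected)
        assert used is fallback

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2,
                    max_size=8))
    def test_never_empty(self, scores):
        labels, used = decide(scores)
        assert labels
        assert used == (max(scores) <= 0)

    def test_prediction_rejects_empty_label_set(self):
        with pytest.raises(ValueError):
            Prediction("P1", (0.0, 0.0), frozenset())
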