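"""Fold plans, out-of-fold stacking, the NNLS convex meta-learner, and the
ensemble's oracle behaviour."""

import numpy as np
import pandas as pd
import pytest

import dynasl.superlearner as sl
from dynasl import (
    LearnerSpec,
    default_library,
    discrete_super_learner,
    fit_super_learner,
    make_fold_plan,
    nnls_meta_learn,
    oof_predictions,
    predict,
)

from conftest import pairwise_auc_bruteforce


def _toy_data(n=120, seed=0, signal=2.0, p_extra=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 1 + p_extra))
    logits = signal * X[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    return X, y


class TestFoldPlan:
    def test_equal_fold_sizes(self):
        y = np.array([0, 1, 0, 1, 0, 1])
        plan = make_fold_plan(6, y, 3, seed=0)
        assert sorted(np.bincount(plan.fold)) == [2, 2, 2]

    def test_stratification_one_event_per_fold(self):
        y = np.array([1, 0, 0, 1, 0, 0, 1, 0, 0])
        plan = make_fold_plan(9, y, 3, seed=0)
        for v in range(3):
            assert y[plan.fold == v].sum() == 1

    def test_same_seed_identical(self):
        y = (np.arange(40) % 3 == 0).astype(int)
        p1 = make_fold_plan(40, y, 5, seed=9)
        p2 = make_fold_plan(40, y, 5, seed=9)
        np.testing.assert_array_equal(p1.fold, p2.fold)

    def test_too_few_events_for_stratification(self):
        y = np.zeros(20)
        y[0] = 1
        with pytest.raises(ValueError, match="events"):
            make_fold_plan(20, y, 5, seed=0)

    def test_n_smaller_than_v(self):
        with pytest.raises(ValueError):
            make_fold_plan(3, np.array([0, 1, 0]), 5)


class TestOOF:
    def test_constant_mean_learner_hand_check(self):
        # a linear-probability model on an all-zero design predicts the
        # training-fold event mean; hand-checkable at n=6, V=3
        X = np.zeros((6, 1))
        y = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        plan = make_fold_plan(6, y, 3, seed=1)
        Z, kept, failures = oof_predictions(
            [LearnerSpec("linear_probability")], X, y, plan
        )
        assert not failures
        for v in range(3):
            train, test = plan.train_test(v)
            np.testing.assert_allclose(Z[test, 0], y[train].mean(), atol=1e-12)

    def test_repeated_call_bit_identical(self):
        X, y = _toy_data(n=60, seed=2)
        plan = make_fold_plan(len(y), y, 3, seed=2)
        lib = [LearnerSpec("logistic"), LearnerSpec("random_forest", {"n_estimators": 30})]
        Z1, _, _ = oof_predictions(lib, X, y, plan, seed=5)
        Z2, _, _ = oof_predictions(lib, X, y, plan, seed=5)
        np.testing.assert_array_equal(Z1, Z2)

    def test_failing_learner_dropped_and_logged(self, monkeypatch):
        class Exploding(sl._BaseLearner):
            def fit(self, X, y):
                raise RuntimeError("boom")

        monkeypatch.setitem(sl._LEARNER_CLASSES, "exploding", Exploding)
        monkeypatch.setattr(sl, "FAMILIES", sl.FAMILIES + ("exploding",))
        X, y = _toy_data(n=40, seed=3)
        plan = make_fold_plan(len(y), y, 2, seed=3)
        lib = [LearnerSpec("logistic"), LearnerSpec("exploding")]
        Z, kept, failures = oof_predictions(lib, X, y, plan)
        assert Z.shape[1] == 1
        assert [s.name for s in kept] == ["logistic"]
        assert failures[0][0] == "exploding" and "boom" in failures[0][1]

    def test_all_learners_failing_is_fatal(self, monkeypatch):
        class Exploding(sl._BaseLearner):
            def fit(self, X, y):
                raise RuntimeError("boom")

        monkeypatch.setitem(sl._LEARNER_CLASSES, "exploding", Exploding)
        monkeypatch.setattr(sl, "FAMILIES", sl.FAMILIES + ("exploding",))
        X, y = _toy_data(n=20, seed=4)
        plan = make_fold_plan(len(y), y, 2, seed=4)
        with pytest.raises(RuntimeError, match="all candidate learners failed"):
            oof_predictions([LearnerSpec("exploding")], X, y, plan)

    def test_z_in_unit_interval(self):
        X, y = _toy_data(n=80, seed=5, signal=4.0)
        plan = make_fold_plan(len(y), y, 4, seed=5)
        Z, _, _ = oof_predictions(
            [LearnerSpec("linear_probability"), LearnerSpec("gam", {"df": 2})],
            X, y, plan,
        )
        assert np.all((Z >= 0) & (Z <= 1))


class TestNNLS:
    def test_exact_column_gets_all_weight(self):
        rng = np.random.default_rng(6)
        y = (rng.random(50) < 0.4).astype(float)
        Z = np.column_stack([rng.random(50), y, rng.random(50)])
        alpha = nnls_meta_learn(Z, y)
        assert alpha[1] == pytest.approx(1.0)
        assert alpha[0] == 0.0 and alpha[2] == 0.0

    def test_single_column(self):
        y = np.array([0.0, 1.0, 1.0])
        assert nnls_meta_learn(y.reshape(-1, 1), y) == pytest.approx([1.0])

    def test_convexity_and_sparsity_preserved(self):
        rng = np.random.default_rng(7)
        y = (rng.random(200) < 0.3).astype(float)
        Z = rng.random((200, 5))
        alpha = nnls_meta_learn(Z, y)
        assert np.all(alpha >= 0)
        assert alpha.sum() == pytest.approx(1.0)
        raw, _ = sl.nnls(Z, y)
        np.testing.assert_array_equal(alpha == 0, raw == 0)

    def test_duplicate_columns_same_fitted_values(self):
        rng = np.random.default_rng(8)
        y = (rng.random(100) < 0.5).astype(float)
        z = rng.random(100)
        single = nnls_meta_learn(z.reshape(-1, 1), y)
        dup = nnls_meta_learn(np.column_stack([z, z]), y)
        np.testing.assert_allclose(
            np.column_stack([z, z]) @ dup, z * single[0], atol=1e-10
        )

    def test_degenerate_z_uniform_fallback(self):
        Z = np.ones((30, 3)) * 0.5
        y = (np.arange(30) % 2).astype(float)
        alpha = nnls_meta_learn(Z, y)
        np.testing.assert_allclose(alpha, 1 / 3)

    def test_objective_at_least_as_good_as_any_single_learner(self):
        rng = np.random.default_rng(9)
        y = (rng.random(300) < 0.4).astype(float)
        Z = np.clip(rng.random((300, 4)) * 0.5 + y[:, None] * 0.3, 0, 1)
        alpha = nnls_meta_learn(Z, y)
        ens = np.sum((y - Z @ alpha) ** 2)
        for l in range(Z.shape[1]):
            single = np.sum((y - Z[:, l]) ** 2)
            assert ens <= single + 1e-8


class TestSuperLearner:
    def test_weights_concentrate_on_oracle_learner(self, monkeypatch):
        class Oracle(sl._BaseLearner):
            def fit(self, X, y):
                return self

            def predict_scores(self, X):
                return (np.asarray(X)[:, 0] > 0).astype(float)

        class Noise(sl._BaseLearner):
            def fit(self, X, y):
                return self

            def predict_scores(self, X):
                return np.random.default_rng(self.seed).random(len(X))

        monkeypatch.setitem(sl._LEARNER_CLASSES, "oracle", Oracle)
        monkeypatch.setitem(sl._LEARNER_CLASSES, "noise", Noise)
        monkeypatch.setattr(sl, "FAMILIES", sl.FAMILIES + ("oracle", "noise"))
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 2))
        y = (X[:, 0] > 0).astype(float)  # separable, oracle is perfect
        fit = fit_super_learner(
            [LearnerSpec("oracle"), LearnerSpec("noise")], X, y, V=5, seed=0
        )
        weights = fit.weights()
        assert weights["oracle"] >= 0.9

    def test_single_learner_library_equivalent_to_learner(self):
        X, y = _toy_data(n=100, seed=11)
        fit = fit_super_learner([LearnerSpec("logistic")], X, y, V=4, seed=1)
        np.testing.assert_allclose(fit.alpha, [1.0])
        direct = sl.build_learner(
            LearnerSpec("logistic"), sl._stable_seed(1, "logistic", "full")
        ).fit(X, y)
        np.testing.assert_allclose(predict(fit, X), direct.predict_scores(X))

    def test_library_order_invariance(self):
        X, y = _toy_data(n=150, seed=12)
        lib = [
            LearnerSpec("logistic"),
            LearnerSpec("linear_probability"),
            LearnerSpec("random_forest", {"n_estimators": 40}),
        ]
        f1 = fit_super_learner(lib, X, y, V=3, seed=2)
        f2 = fit_super_learner(lib[::-1], X, y, V=3, seed=2)
        np.testing.assert_allclose(predict(f1, X), predict(f2, X), atol=1e-10)

    def test_deterministic_alpha_across_runs(self):
        X, y = _toy_data(n=100, seed=13)
        lib = [LearnerSpec("logistic"), LearnerSpec("random_forest", {"n_estimators": 40})]
        a1 = fit_super_learner(lib, X, y, V=4, seed=3).alpha
        a2 = fit_super_learner(lib, X, y, V=4, seed=3).alpha
        np.testing.assert_array_equal(a1, a2)

    def test_default_library_fits(self):
        X, y = _toy_data(n=150, seed=14, p_extra=2)
        fit = fit_super_learner(default_library(), X, y, V=3, seed=4)
        assert np.all(fit.alpha >= 0)
        assert fit.alpha.sum() == pytest.approx(1.0)
        p = predict(fit, X)
        assert np.all((p >= 0) & (p <= 1))


class TestPredict:
    def test_constant_learner_full_weight(self, monkeypatch):
        class Const(sl._BaseLearner):
            def fit(self, X, y):
                return self

            def predict_scores(self, X):
                return np.full(len(X), 0.3)

        monkeypatch.setitem(sl._LEARNER_CLASSES, "const", Const)
        monkeypatch.setattr(sl, "FAMILIES", sl.FAMILIES + ("const",))
        spec = LearnerSpec("const")
        noise = LearnerSpec("linear_probability")
        fit = sl.SuperLearnerFit(
            library=[spec, noise],
            learners={"const": Const(spec, 0), "linear_probability": None},
            alpha=np.array([1.0, 0.0]),
            plan=None, Z=None, feature_names=None, failures=[],
        )
        np.testing.assert_allclose(predict(fit, np.zeros((4, 2))), 0.3)

    def test_hand_computed_convex_combination(self, monkeypatch):
        class A(sl._BaseLearner):
            def fit(self, X, y):
                return self

            def predict_scores(self, X):
                return np.array([0.2, 0.4, 0.6])

        class B(sl._BaseLearner):
            def fit(self, X, y):
                return self

            def predict_scores(self, X):
                return np.array([1.0, 0.0, 0.5])

        sa, sb = LearnerSpec("logistic", name="A"), LearnerSpec("logistic", name="B")
        fit = sl.SuperLearnerFit(
            library=[sa, sb],
            learners={"A": A(sa, 0), "B": B(sb, 0)},
            alpha=np.array([0.25, 0.75]),
            plan=None, Z=None, feature_names=None, failures=[],
        )
        expected = 0.25 * np.array([0.2, 0.4, 0.6]) + 0.75 * np.array([1.0, 0.0, 0.5])
        np.testing.assert_allclose(predict(fit, np.zeros((3, 1))), expected)

    def test_column_mismatch_lists_missing_and_extra(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": [1.0, 0.0, 1.0, 0.0]})
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_super_learner([LearnerSpec("linear_probability")], X, y, V=2, seed=0)
        bad = pd.DataFrame({"a": [0.0], "c": [1.0]})
        with pytest.raises(ValueError, match="missing.*b.*extra.*c"):
            predict(fit, bad)


class TestDiscreteSuperLearner:
    def test_exact_column_selected(self):
        rng = np.random.default_rng(15)
        y = (rng.random(40) < 0.5).astype(float)
        Z = np.column_stack([rng.random(40), y])
        assert discrete_super_learner(Z, y) == 1

    def test_ties_break_to_lower_index(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        z = np.array([0.1, 0.9, 0.2, 0.8])
        assert discrete_super_learner(np.column_stack([z, z]), y) == 0

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            y = (rng.random(20) < 0.5).astype(float)
            if y.sum() in (0, 20):
                continue
            Z = rng.random((20, 3))
            aucs = [pairwise_auc_bruteforce(Z[:, l], y) for l in range(3)]
            assert discrete_super_learner(Z, y) == int(np.argmax(aucs))
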