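import numpy as np
import pandas as pd
import pytest

from histotex.features import FeatureTable
from histotex.learn import (BoostTrace, ClassifierSpec, adaboost_train,
                            bagging_train, baseline_train, cross_validate)


def blobs(n_per=15, seed=0, spread=0.5):
    rng = np.random.default_rng(seed)
    centres = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0], [6.0, 6.0]])
    x = np.vstack([c + rng.normal(0, spread, (n_per, 2)) for c in centres])
    y = np.repeat([1, 2, 3, 4], n_per)
    return x, y


def blob_table(n_per=15, seed=0, spread=0.5):
    x, y = blobs(n_per, seed, spread)
    return FeatureTable(pd.DataFrame(x, columns=["f0", "f1"]), y)


class _AlwaysOne:
    """Weak learner predicting class 1 regardless of input."""

    def fit(self, x, y):
        return self

    def predict(self, x):
        return np.ones(len(x), dtype=int)


class _PerfectRule:
    """Learner that is always right on x = [[1],[1],[2],[2]], y = [1,1,2,2]."""

    def fit(self, x, y):
        return self

    def predict(self, x):
        return np.where(np.asarray(x)[:, 0] < 1.5, 1, 2)


class TestBagging:
    def test_separable_blobs_train_accuracy(self):
        x, y = blobs()
        model = bagging_train(x, y, n_members=15, seed=0)
        assert (model.predict(x) == y).mean() == 1.0

    def test_majority_support_is_vote_fraction(self):
        x, y = blobs()
        model = bagging_train(x, y, n_members=10, seed=0)
        s = model.support(x[:5])
        np.testing.assert_allclose(s.sum(axis=1), 1.0)
        assert s.min() >= 0

    def test_deterministic_given_seed(self):
        x, y = blobs()
        a = bagging_train(x, y, 8, seed=7).predict(x)
        b = bagging_train(x, y, 8, seed=7).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_rejects_empty_ensemble(self):
        x, y = blobs()
        with pytest.raises(ValueError):
            bagging_train(x, y, n_members=0)


class TestAdaBoost:
    def test_hand_traced_weight_update(self):
        # 4 samples, constant class-1 learner, one sample of class 2:
        # round 1: ε = 1/4, β = 1/3, correct weights ×β → w = (1/6,1/6,1/6,1/2)
        # round 2: ε = 1/2 → discard and reset to uniform
        # round 3: ε = 1/4 again → second member retained
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 1, 2])
        trace = BoostTrace()
        model = adaboost_train(x, y, n_members=2, seed=0,
                               base_learner=lambda s: _AlwaysOne(), trace=trace)
        assert trace.epsilons == pytest.approx([0.25, 0.5, 0.25])
        assert trace.retained == [True, False, True]
        assert trace.betas[0] == pytest.approx(1 / 3)
        assert np.isnan(trace.betas[1])
        np.testing.assert_allclose(trace.weights[1], [1 / 6, 1 / 6, 1 / 6, 1 / 2])
        np.testing.assert_allclose(trace.weights[2], 0.25)
        assert model.member_weights == pytest.approx([np.log(3), np.log(3)])

    def test_perfect_learner_rounds_all_discarded(self):
        x = np.array([[1.0], [1.0], [2.0], [2.0]])
        y = np.array([1, 1, 2, 2])
        trace = BoostTrace()
        model = adaboost_train(x, y, n_members=3, seed=0,
                               base_learner=lambda s: _PerfectRule(),
                               max_attempts=6, trace=trace)
        assert trace.retained == [False] * 6
        assert trace.epsilons == pytest.approx([0.0] * 6)
        # the ε = 0 discard rule rejected every round; the single-learner
        # fallback keeps the model usable
        assert len(model.members) == 1
        np.testing.assert_array_equal(model.predict(x), y)

    def test_weighted_support_sums_member_log_inv_beta(self):
        x, y = blobs(spread=1.6, seed=1)
        model = adaboost_train(x, y, n_members=10, seed=0)
        assert len(model.members) >= 1
        s = model.support(x[:6])
        np.testing.assert_allclose(s.sum(axis=1), sum(model.member_weights))

    def test_learns_separable_blobs(self):
        x, y = blobs()
        model = adaboost_train(x, y, n_members=20, seed=0)
        assert (model.predict(x) == y).mean() == 1.0


class TestBaselines:
    @pytest.mark.parametrize("kind", ["fisher", "svm_linear", "random_forest"])
    def test_separable_blobs(self, kind):
        x, y = blobs()
        model = baseline_train(x, y, kind, seed=0)
        assert (model.predict(x) == y).mean() == 1.0

    def test_fisher_two_class_sign_rule(self):
        x = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([0, 0, 1, 1])
        model = baseline_train(x, y, "fisher")
        np.testing.assert_array_equal(model.predict(x), y)

    def test_unknown_kind_rejected(self):
        x, y = blobs(4)
        with pytest.raises(ValueError):
            baseline_train(x, y, "mlp")


class TestCrossValidate:
    def test_each_sample_predicted_once_with_fold_labels(self):
        table = blob_table()
        res = cross_validate(table, ClassifierSpec(kind="fisher"), folds=5, seed=0)
        assert len(res.predictions) == len(table)
        assert set(res.fold_assignment) == set(range(5))

    def test_stratified_folds_balanced(self):
        table = blob_table(n_per=20)
        res = cross_validate(table, ClassifierSpec(kind="fisher"), folds=5, seed=1)
        for fold in range(5):
            labs = res.truth[res.fold_assignment == fold]
            assert list(np.bincount(labs)[1:]) == [4, 4, 4, 4]

    @pytest.mark.parametrize("kind,members", [("bagging", 10), ("adaboost", 10),
                                              ("fisher", 1), ("svm_linear", 1),
                                              ("random_forest", 10)])
    def test_high_accuracy_on_separable_data(self, kind, members):
        table = blob_table()
        res = cross_validate(table, ClassifierSpec(kind=kind, n_members=members),
                             folds=4, seed=0)
        assert res.accuracy >= 0.95

    def test_fold_safe_reduction_drops_duplicate_column(self):
        x, y = blobs()
        frame = pd.DataFrame({"f0": x[:, 0], "f1": x[:, 1], "dup": x[:, 0]})
        table = FeatureTable(frame, y)
        spec = ClassifierSpec(kind="fisher", reduce_threshold=0.97)
        res = cross_validate(table, spec, folds=3, seed=0)
        assert res.accuracy >= 0.95

    def test_paper_mode_reduction_matches_prefiltered_run(self):
        from histotex.reduce import apply_filter, fit_correlation_filter
        x, y = blobs()
        frame = pd.DataFrame({"f0": x[:, 0], "f1": x[:, 1], "dup": 2 * x[:, 0]})
        table = FeatureTable(frame, y)
        spec = ClassifierSpec(kind="fisher", reduce_threshold=0.97, paper_mode=True)
        res = cross_validate(table, spec, folds=3, seed=5)
        pre = apply_filter(table, fit_correlation_filter(table, 0.97))
        res2 = cross_validate(pre, ClassifierSpec(kind="fisher"), folds=3, seed=5)
        np.testing.assert_array_equal(res.predictions, res2.predictions)

    def test_deterministic_given_seed(self):
        table = blob_table()
        a = cross_validate(table, ClassifierSpec(kind="bagging", n_members=5),
                           folds=3, seed=9)
        b = cross_validate(table, ClassifierSpec(kind="bagging", n_members=5),
                           folds=3, seed=9)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(blob_table(), ClassifierSpec(), folds=1)
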