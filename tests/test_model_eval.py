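import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetpath import (
    ClassifierSpec,
    ConfusionCounts,
    FeatureTable,
    evaluate,
    evaluate_scores,
    f1_score,
    predict_scores,
    roc_auc,
    tune_and_train,
)
from hetpath.model_eval import confusion_at_threshold


def pairwise_auc(scores, labels):
    """Mann-Whitney oracle: fraction of pos-neg pairs ordered correctly, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _table(X, name="custom"):
    cols = [f"f{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "disease_id", [f"s{i}" for i in range(len(X))])
    frame.insert(0, "domain_id", [f"d{i}" for i in range(len(X))])
    return FeatureTable(frame, cols, name)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = [1, 1, 0, 0]
        assert roc_auc(labels, labels)[0] == 1.0
        assert roc_auc([1 - l for l in labels], labels)[0] == 0.0

    def test_tied_scores_get_half_credit(self):
        auc, _ = roc_auc([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.875)
        assert auc == pytest.approx(pairwise_auc([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0]))

    def test_constant_scores_are_chance(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([0.2, 0.8], [1, 1])

    def test_curve_endpoints(self):
        _, points = roc_auc([0.9, 0.1, 0.6], [1, 0, 1])
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # quantized scores force plenty of ties
        scores = np.round(rng.random(n), 1)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.random(30)
        base, _ = roc_auc(scores, labels)
        warped, _ = roc_auc(np.exp(3 * scores) - 0.5, labels)
        assert warped == pytest.approx(base, abs=1e-12)


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(2, 1, 1, 2 / 3), (0, 0, 5, 0.0), (10, 0, 0, 1.0)],
    )
    def test_direct_formula(self, tp, fp, fn, expected):
        assert f1_score(ConfusionCounts(tp, fp, fn, 0)) == pytest.approx(expected)

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert f1_score(ConfusionCounts(0, 0, 0, 7)) == 0.0

    @given(
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=0, max_value=100),
    )
    @settings(deadline=None, derandomize=True)
    def test_equals_harmonic_mean_when_defined(self, tp, fp, fn):
        if tp + fp == 0 or tp + fn == 0 or tp == 0:
            return
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        harmonic = 2 * precision * recall / (precision + recall)
        assert f1_score(ConfusionCounts(tp, fp, fn, 0)) == pytest.approx(harmonic)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_confusion_partitions_all_pairs(self):
        scores = [0.9, 0.6, 0.4, 0.2, 0.5]
        labels = [1, 0, 1, 0, 1]
        c = confusion_at_threshold(scores, labels, 0.5)
        assert c.total == 5
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 1, 1)


class TestTuneAndTrain:
    def _separable(self, n=30):
        X = np.vstack([np.ones((n, 3)), np.zeros((n, 3))])
        y = np.array([1] * n + [0] * n)
        return _table(X), y

    def test_single_combination_grid_is_best(self):
        table, y = self._separable()
        spec = ClassifierSpec("gbt", {"n_estimators": [50], "max_depth": [2]}, seed=0)
        model = tune_and_train(table, y, spec)
        assert model.best_params == {"n_estimators": 50, "max_depth": 2}
        assert np.isfinite(model.cv_mean_auc)

    def test_separable_data_training_auc_is_one(self):
        table, y = self._separable()
        spec = ClassifierSpec("gbt", {"n_estimators": [50]}, seed=0)
        model = tune_and_train(table, y, spec)
        scores = predict_scores(model, table)
        assert roc_auc(scores, y)[0] == 1.0

    def test_same_seed_reproduces_best_params_and_scores(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 4))
        y = (X[:, 0] + 0.3 * rng.random(60) > 0.6).astype(int)
        table = _table(X)
        spec = ClassifierSpec(
            "gbt", {"n_estimators": [20, 40], "max_depth": [2, 3]}, seed=7
        )
        a = tune_and_train(table, y, spec)
        b = tune_and_train(table, y, spec)
        assert a.best_params == b.best_params
        np.testing.assert_array_equal(predict_scores(a, table), predict_scores(b, table))

    def test_single_class_labels_rejected(self):
        table, _ = self._separable()
        with pytest.raises(ValueError, match="both classes"):
            tune_and_train(table, np.ones(len(table)), ClassifierSpec("gbt", {"n_estimators": [10]}))

    @pytest.mark.parametrize("algorithm", ["rf", "svm", "nb"])
    def test_baselines_fit_and_score(self, algorithm):
        table, y = self._separable(20)
        model = tune_and_train(table, y, ClassifierSpec(algorithm, seed=1))
        scores = predict_scores(model, table)
        assert roc_auc(scores, y)[0] == 1.0

    def test_unknown_gbt_grid_key_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            ClassifierSpec("gbt", {"learning_rate": [0.1]})


class TestPredictScores:
    def _model(self):
        table, y = TestTuneAndTrain()._separable(10)
        return tune_and_train(table, y, ClassifierSpec("gbt", {"n_estimators": [10]})), table

    def test_zero_row_table_gives_empty_scores(self):
        model, table = self._model()
        empty = FeatureTable(table.frame.iloc[:0], table.feature_columns)
        assert len(predict_scores(model, empty)) == 0

    def test_duplicated_row_duplicates_score(self):
        model, table = self._model()
        dup = FeatureTable(
            pd.concat([table.frame.iloc[[0]], table.frame.iloc[[0]]]),
            table.feature_columns,
        )
        scores = predict_scores(model, dup)
        assert scores[0] == scores[1]

    def test_column_permutation_is_schema_error(self):
        model, table = self._model()
        permuted = FeatureTable(table.frame, table.feature_columns[::-1])
        with pytest.raises(ValueError, match="columns"):
            predict_scores(model, permuted)


class TestEvaluate:
    def test_perfect_scores_report(self):
        report = evaluate_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert report.auc == 1.0 and report.f1 == 1.0
        assert report.roc_points[0] == (0.0, 0.0)
        assert report.roc_points[-1] == (1.0, 1.0)

    def test_constant_scores_tie_convention(self):
        report = evaluate_scores([0.5] * 4, [1, 0, 1, 0], threshold=0.5)
        assert report.auc == pytest.approx(0.5)
        # all predicted positive at threshold 0.5
        assert report.confusion.TP == 2 and report.confusion.FP == 2
        assert report.f1 == pytest.approx(2 * 2 / (2 * 2 + 0 + 2))

    def test_end_to_end_with_model(self):
        table, y = TestTuneAndTrain()._separable(12)
        model = tune_and_train(table, y, ClassifierSpec("gbt", {"n_estimators": [10]}))
        report = evaluate(model, table, y)
        assert report.auc == 1.0
        assert report.to_dict()["confusion"]["TP"] == 12
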