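"""Classifier: stratified split, grid-search bookkeeping, evaluation."""

import numpy as np
import pytest

from ccsfp._search import (
    DEFAULT_CLASSIFIER_GRID,
    DEFAULT_REGRESSOR_GRID,
    HyperparameterGrid,
    evenly_spaced_ints,
    select_best_candidate,
)
from ccsfp.classify import (
    SuperClassClassifier,
    evaluate_classifier,
    stratified_split,
    train_classifier,
)

SMALL_GRID = HyperparameterGrid((30,), (2,))


class TestStratifiedSplit:
    def test_largest_remainder_examples(self):
        labels = np.array(["A"] * 227)
        train, test = stratified_split(labels, test_frac=0.2, seed=0)
        assert test.size == 46  # 227 -> 181 train + 46 test
        labels = np.array(["A"] * 10)
        assert stratified_split(labels, 0.2, seed=0)[1].size == 2

    def test_five_class_apportionment(self):
        sizes = {"Benzenoids": 227, "Lipids": 236, "Acids": 230, "Oxygen": 178, "Hetero": 175}
        labels = np.concatenate([[name] * size for name, size in sizes.items()])
        train, test = stratified_split(labels, test_frac=0.2, seed=3)
        test_counts = {name: int((labels[test] == name).sum()) for name in sizes}
        assert test_counts == {
            "Benzenoids": 46,
            "Lipids": 47,
            "Acids": 46,
            "Oxygen": 36,
            "Hetero": 35,
        }
        assert train.size == 836 and test.size == 210

    def test_deterministic_and_disjoint(self):
        labels = np.array(["A"] * 30 + ["B"] * 20)
        a = stratified_split(labels, 0.2, seed=11)
        b = stratified_split(labels, 0.2, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert set(a[0]) | set(a[1]) == set(range(50))
        assert not set(a[0]) & set(a[1])

    def test_class_proportions_within_one(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["A", "B", "C"], size=101, p=[0.5, 0.3, 0.2])
        _, test = stratified_split(labels, 0.25, seed=5)
        for name in "ABC":
            size = int((labels == name).sum())
            got = int((labels[test] == name).sum())
            assert abs(got - 0.25 * size) <= 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="'B'"):
            stratified_split(np.array(["A", "A", "A", "B"]), 0.2, seed=0)


class TestGrids:
    def test_default_grid_shapes(self):
        assert DEFAULT_CLASSIFIER_GRID.n_candidates == 25
        assert DEFAULT_CLASSIFIER_GRID.n_estimators_values == (100, 125, 150, 175, 200)
        assert DEFAULT_CLASSIFIER_GRID.min_samples_leaf_values == (2, 5, 9, 12, 15)
        assert DEFAULT_REGRESSOR_GRID.n_candidates == 50
        assert DEFAULT_REGRESSOR_GRID.n_estimators_values[0] == 100
        assert DEFAULT_REGRESSOR_GRID.n_estimators_values[-1] == 500
        assert DEFAULT_REGRESSOR_GRID.min_samples_leaf_values == (5, 9, 13, 16, 20)

    def test_evenly_spaced_validation(self):
        assert evenly_spaced_ints(2, 15, 5) == [2, 5, 9, 12, 15]
        with pytest.raises(ValueError):
            evenly_spaced_ints(1, 3, 10)

    def test_best_candidate_tie_break(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "n_estimators": [100, 200, 100],
                "min_samples_leaf": [2, 5, 9],
                "mean_cv_score": [0.9, 0.9, 0.9],
            }
        )
        best = select_best_candidate(table)
        assert best == {"n_estimators": 100, "min_samples_leaf": 9}


def separable_data(n_per_class=30, seed=0):
    """Two classes determined by disjoint informative bits."""
    rng = np.random.default_rng(seed)
    X = (rng.random((2 * n_per_class, 64)) < 0.1).astype(np.uint8)
    X[:n_per_class, 3] = 1
    X[:n_per_class, 7] = 0
    X[n_per_class:, 7] = 1
    X[n_per_class:, 3] = 0
    y = np.array(["low"] * n_per_class + ["high"] * n_per_class)
    return X, y


class TestTrainClassifier:
    def test_cv_table_has_one_row_per_candidate(self):
        X, y = separable_data()
        grid = HyperparameterGrid((10, 20), (2, 3, 4))
        results = train_classifier(X, y, grid=grid, cv_folds=3, seed=0)
        assert len(results.cv_table) == grid.n_candidates == 6
        assert {"split0_score", "split1_score", "split2_score"} <= set(results.cv_table.columns)

    def test_separable_classes_reach_perfect_cv(self):
        X, y = separable_data()
        results = train_classifier(X, y, grid=SMALL_GRID, cv_folds=5, seed=0)
        assert results.best_cv_score == 1.0

    def test_best_params_member_of_grid(self):
        X, y = separable_data()
        grid = HyperparameterGrid((10, 25), (2, 4))
        results = train_classifier(X, y, grid=grid, cv_folds=3, seed=0)
        assert results.best_params["n_estimators"] in grid.n_estimators_values
        assert results.best_params["min_samples_leaf"] in grid.min_samples_leaf_values

    def test_cv_folds_exceeding_smallest_class_rejected(self):
        X, y = separable_data(n_per_class=4)
        with pytest.raises(ValueError, match="smallest class"):
            train_classifier(X, y, grid=SMALL_GRID, cv_folds=5, seed=0)

    def test_same_seed_reproduces_predictions(self):
        X, y = separable_data(seed=2)
        a = train_classifier(X, y, grid=SMALL_GRID, cv_folds=3, seed=9)
        b = train_classifier(X, y, grid=SMALL_GRID, cv_folds=3, seed=9)
        assert np.array_equal(a.predict(X), b.predict(X))
        assert a.cv_table.equals(b.cv_table)

    def test_summary_mentions_key_facts(self):
        X, y = separable_data()
        results = train_classifier(X, y, grid=SMALL_GRID, cv_folds=3, seed=0)
        text = results.summary()
        assert "n_estimators" in text and "seed" in text


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        X, y = separable_data()
        results = train_classifier(X, y, grid=SMALL_GRID, cv_folds=3, seed=0)
        report = evaluate_classifier(results, X, y)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.per_class_f1.values())

    def test_f1_worked_example(self):
        # one-vs-rest with TP=40, FP=5, FN=6 -> F1 = 2PR/(P+R) ~ 0.879
        precision, recall = 40 / 45, 40 / 46
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 == pytest.approx(0.879, abs=5e-4)
        y_true = np.array(["P"] * 46 + ["N"] * 60)
        y_pred = np.array(["P"] * 40 + ["N"] * 6 + ["P"] * 5 + ["N"] * 55)
        from sklearn.metrics import f1_score

        assert f1_score(y_true, y_pred, pos_label="P") == pytest.approx(f1)

    def test_confusion_matrix_invariants(self, synthetic_features):
        X, families, _, _ = synthetic_features
        train, test = stratified_split(families, 0.25, seed=1)
        results = train_classifier(X[train], families[train], grid=SMALL_GRID, cv_folds=3, seed=1)
        report = results.evaluate(X[test], families[test])
        assert report.confusion.sum() == test.size
        assert np.trace(report.confusion) / report.confusion.sum() == pytest.approx(
            report.accuracy
        )
        row_sums = report.confusion.sum(axis=1)
        for name, total in zip(report.classes, row_sums):
            assert total == int((families[test] == name).sum())

    def test_unknown_test_class_rejected(self):
        X, y = separable_data()
        results = train_classifier(X, y, grid=SMALL_GRID, cv_folds=3, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            results.evaluate(X[:2], np.array(["mystery", "low"]))


def test_model_from_dataframe(synthetic_features):
    import pandas as pd

    _, families, _, fps = synthetic_features
    df = pd.DataFrame({"fp": fps, "assigned_class": families})
    model = SuperClassClassifier.from_dataframe(df, grid=SMALL_GRID, seed=0)
    assert model.X.shape == (len(fps), 1024)
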