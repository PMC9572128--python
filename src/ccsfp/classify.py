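"""Random-forest super-class classification from fingerprints.

The model is organised like a statsmodels estimator: build a
:class:`SuperClassClassifier` from a feature matrix (or fingerprints) and
labels, call :meth:`~SuperClassClassifier.fit` to run the grid-searched
cross-validation, and work with the returned
:class:`SuperClassClassifierResults` (best hyperparameters, per-candidate CV
table, prediction, evaluation, ``summary()``).

The default search follows the study design for this model family: 25
candidates over 100-200 trees and minimum leaf sizes 2-15, scored by mean
accuracy over 5 stratified folds, trained on a stratified 80/20 split.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from ._search import (
    DEFAULT_CLASSIFIER_GRID,
    HyperparameterGrid,
    cv_table_from_results,
    select_best_candidate,
)
from .fingerprints import FingerprintVector, fingerprint_matrix

DEFAULT_SEED = 42


def _as_matrix(X) -> np.ndarray:
    if len(X) and isinstance(X[0], FingerprintVector):
        return fingerprint_matrix(X)
    return np.asarray(X)


def stratified_split(
    labels: Sequence[str],
    test_frac: float = 0.2,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified index split with largest-remainder rounding.

    The total test size is ``n - floor((1 - test_frac) * n)`` and is
    apportioned to classes by the largest-remainder method: each class
    contributes ``floor(test_frac * size)`` test members, and the remaining
    seats go to the classes with the largest fractional remainders (ties by
    class name).  Within a class, membership is drawn by a seeded permutation.

    Returns ``(train_idx, test_idx)`` index arrays.
    """
    if not (0 < test_frac < 1):
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    labels = np.asarray(labels)
    n = labels.size
    counts = Counter(labels.tolist())
    for name, size in counts.items():
        if size < 2:
            raise ValueError(f"class {name!r} has fewer than 2 members")
    total_test = n - math.floor((1 - test_frac) * n + 1e-9)
    names = sorted(counts)
    base = {c: math.floor(test_frac * counts[c] + 1e-9) for c in names}
    remainder = {c: test_frac * counts[c] - base[c] for c in names}
    extras = total_test - sum(base.values())
    for c in sorted(names, key=lambda c: (-remainder[c], c)):
        if extras <= 0:
            break
        if base[c] + 1 <= counts[c] - 1:  # keep at least one train member
            base[c] += 1
            extras -= 1
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(n, dtype=bool)
    for c in names:
        idx = np.flatnonzero(labels == c)
        chosen = rng.permutation(idx)[: base[c]]
        test_mask[chosen] = True
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


@dataclass
class ClassificationReport:
    """Test-set evaluation: accuracy, one-vs-rest F1 per class, confusion matrix."""

    accuracy: float
    per_class_f1: dict[str, float]
    confusion: np.ndarray  # rows = true class, columns = predicted class
    classes: list[str]
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        support = self.confusion.sum(axis=1)
        correct = np.diag(self.confusion)
        return pd.DataFrame(
            {
                "super_class": self.classes,
                "n_test": support,
                "f1_score": [self.per_class_f1[c] for c in self.classes],
                "class_accuracy": np.where(support > 0, correct / np.maximum(support, 1), np.nan),
            }
        )

    def confusion_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


class SuperClassClassifier:
    """Random-forest chemical super-class model over fingerprint bits.

    Parameters
    ----------
    X:
        Feature matrix (n_samples, n_bits) of 0/1 fingerprint bits, or a
        sequence of :class:`~ccsfp.fingerprints.FingerprintVector`.
    y:
        Super-class label per sample.
    grid:
        Hyperparameter grid searched during :meth:`fit`; defaults to the
        25-candidate grid (trees 100-200, leaf 2-15).
    seed:
        Master seed controlling fold assignment and forest randomness.
    """

    def __init__(
        self,
        X,
        y: Sequence[str],
        grid: HyperparameterGrid = DEFAULT_CLASSIFIER_GRID,
        seed: int = DEFAULT_SEED,
    ) -> None:
        self.X = _as_matrix(X)
        self.y = np.asarray(y)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y lengths differ")
        if self.X.shape[0] == 0:
            raise ValueError("empty training set")
        self.grid = grid
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fp_column: str = "fp", label_column: str = "assigned_class", **kwargs
    ) -> "SuperClassClassifier":
        return cls(list(df[fp_column]), df[label_column].to_numpy(), **kwargs)

    def fit(self, cv_folds: int = 5) -> "SuperClassClassifierResults":
        """Grid-search by mean CV accuracy, refit the best candidate on all data."""
        smallest = min(Counter(self.y.tolist()).values())
        if cv_folds > smallest:
            raise ValueError(
                f"cv_folds={cv_folds} exceeds the smallest class count ({smallest})"
            )
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(
            RandomForestClassifier(random_state=self.seed, n_jobs=1),
            self.grid.to_param_grid(),
            scoring="accuracy",
            cv=cv,
            refit=False,
            n_jobs=1,
        )
        search.fit(self.X, self.y)
        cv_table = cv_table_from_results(search.cv_results_, cv_folds)
        best = select_best_candidate(cv_table)
        estimator = RandomForestClassifier(
            random_state=self.seed, n_jobs=1, **best
        ).fit(self.X, self.y)
        return SuperClassClassifierResults(
            model=self,
            estimator=estimator,
            best_params=best,
            cv_table=cv_table,
            cv_folds=cv_folds,
        )


@dataclass
class SuperClassClassifierResults:
    """Fitted super-class classifier with its CV record."""

    model: SuperClassClassifier
    estimator: RandomForestClassifier
    best_params: dict[str, int]
    cv_table: pd.DataFrame
    cv_folds: int

    @property
    def classes_(self) -> list[str]:
        return list(self.estimator.classes_)

    @property
    def best_cv_score(self) -> float:
        return float(self.cv_table["mean_cv_score"].max())

    @property
    def seed(self) -> int:
        return self.model.seed

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(_as_matrix(X))

    def evaluate(self, X_test, y_test: Sequence[str]) -> ClassificationReport:
        """Accuracy, per-class F1 and confusion matrix on a held-out test set."""
        X_test = _as_matrix(X_test)
        y_test = np.asarray(y_test)
        if y_test.size == 0:
            raise ValueError("empty test set")
        unknown = sorted(set(y_test.tolist()) - set(self.classes_))
        if unknown:
            raise ValueError(f"test classes unknown to the model: {unknown}")
        y_pred = self.estimator.predict(X_test)
        conf = confusion_matrix(y_test, y_pred, labels=self.classes_)
        f1 = f1_score(y_test, y_pred, labels=self.classes_, average=None, zero_division=0)
        return ClassificationReport(
            accuracy=float((y_pred == y_test).mean()),
            per_class_f1={c: float(v) for c, v in zip(self.classes_, f1)},
            confusion=conf,
            classes=self.classes_,
            n=int(y_test.size),
        )

    def summary(self) -> str:
        lines = [
            "Super-class random forest classifier",
            "=" * 40,
            f"n_samples:        {self.model.X.shape[0]}",
            f"n_features:       {self.model.X.shape[1]}",
            f"classes:          {', '.join(self.classes_)}",
            f"grid candidates:  {self.model.grid.n_candidates}",
            f"cv folds:         {self.cv_folds}",
            f"best n_estimators:     {self.best_params['n_estimators']}",
            f"best min_samples_leaf: {self.best_params['min_samples_leaf']}",
            f"best mean CV accuracy: {self.best_cv_score:.4f}",
            f"seed:             {self.seed}",
        ]
        return "\n".join(lines)


def train_classifier(
    X,
    y: Sequence[str],
    grid: HyperparameterGrid = DEFAULT_CLASSIFIER_GRID,
    cv_folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> SuperClassClassifierResults:
    """Grid-searched CV training of the super-class classifier (functional surface)."""
    return SuperClassClassifier(X, y, grid=grid, seed=seed).fit(cv_folds=cv_folds)


def evaluate_classifier(
    results: SuperClassClassifierResults, X_test, y_test: Sequence[str]
) -> ClassificationReport:
    """Evaluate a fitted classifier on a held-out test set (functional surface)."""
    return results.evaluate(X_test, y_test)
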