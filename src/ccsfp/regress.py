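"""Random-forest CCS regression from fingerprints.

Two regression strategies share this module:

* a *direct* model trained on the full curated dataset, and
* *class-based* models, one per consolidated super class, applied after the
  classifier routes a chemical to its class.

Both are :class:`CCSRegressor` instances (statsmodels-style: model object,
``fit()`` returns a :class:`CCSRegressorResults`), differing only in their
``scope``.  The default search follows the study design: 50 candidates over
100-500 trees and minimum leaf sizes 5-20, scored by mean CV R² over 5 folds.

Because a random forest predicts by averaging training targets, every
prediction lies inside the training-target range; :meth:`CCSRegressorResults.predict`
asserts this invariant on every call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold

from ._search import (
    DEFAULT_REGRESSOR_GRID,
    HyperparameterGrid,
    cv_table_from_results,
    select_best_candidate,
)
from .classify import DEFAULT_SEED, SuperClassClassifierResults, _as_matrix
from .curate import canonicalize_smiles
from .fingerprints import N_BITS_DEFAULT, tt_fingerprint

#: Scope label of the model trained on the full dataset.
DIRECT = "direct"

#: Default within-x% reporting thresholds (percent relative error).
DEFAULT_WITHIN_THRESHOLDS = (1.0, 3.0, 5.0, 7.0, 8.0)


def relative_error(y_true: float, y_pred: float) -> tuple[float, float]:
    """Residual (Å²) and absolute relative error (%) of one prediction.

    residual = predicted − true; relative = 100·|predicted − true| / true.
    """
    if not (y_true > 0):
        raise ValueError(f"true CCS must be positive, got {y_true}")
    residual = y_pred - y_true
    return residual, 100.0 * abs(residual) / y_true


@dataclass
class RegressionReport:
    """Regression test metrics: R², median relative error, residual diagnostics."""

    r2: float
    mre_pct: float
    residuals: pd.DataFrame  # columns: y_true, y_pred, residual, rel_err_pct
    within_pct: dict[float, float]
    n: int

    def residual_quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.Series:
        return self.residuals["residual"].quantile(list(q))

    def outliers(self, rel_err_threshold_pct: float = 10.0) -> pd.DataFrame:
        """Records whose relative error exceeds the threshold."""
        return self.residuals[self.residuals["rel_err_pct"] >= rel_err_threshold_pct]


def evaluate_predictions(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    within_thresholds: Sequence[float] = DEFAULT_WITHIN_THRESHOLDS,
) -> RegressionReport:
    """Build a :class:`RegressionReport` from paired true/predicted CCS values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if (y_true <= 0).any():
        raise ValueError("true CCS values must be positive")
    residual = y_pred - y_true
    rel = 100.0 * np.abs(residual) / y_true
    if np.allclose(y_true, y_true[0]):
        warnings.warn("zero-variance test targets: R² is undefined", RuntimeWarning)
        r2 = float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
    return RegressionReport(
        r2=r2,
        mre_pct=float(np.median(rel)),
        residuals=pd.DataFrame(
            {"y_true": y_true, "y_pred": y_pred, "residual": residual, "rel_err_pct": rel}
        ),
        within_pct={float(t): float((rel <= t).mean()) for t in within_thresholds},
        n=int(y_true.size),
    )


class CCSRegressor:
    """Random-forest CCS model over fingerprint bits.

    Parameters
    ----------
    X:
        Feature matrix (n_samples, n_bits) of 0/1 bits, or fingerprints.
    y:
        Measured CCS targets (Å², positive).
    scope:
        ``"direct"`` for the full-dataset model, or a super-class label for a
        class-based model.
    grid, seed:
        Search grid (default: 50 candidates, trees 100-500, leaf 5-20) and
        master seed.
    """

    def __init__(
        self,
        X,
        y: Sequence[float],
        scope: str = DIRECT,
        grid: HyperparameterGrid = DEFAULT_REGRESSOR_GRID,
        seed: int = DEFAULT_SEED,
    ) -> None:
        self.X = _as_matrix(X)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y lengths differ")
        if self.X.shape[0] == 0:
            raise ValueError("empty training set")
        if (self.y <= 0).any():
            raise ValueError("CCS targets must be positive")
        self.scope = scope
        self.grid = grid
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fp_column: str = "fp", target_column: str = "ccs", **kwargs
    ) -> "CCSRegressor":
        return cls(list(df[fp_column]), df[target_column].to_numpy(), **kwargs)

    def fit(self, cv_folds: int = 5) -> "CCSRegressorResults":
        """Grid-search by mean CV R², refit the best candidate on all data."""
        if self.X.shape[0] < cv_folds:
            raise ValueError(
                f"training set of {self.X.shape[0]} smaller than cv_folds={cv_folds}"
            )
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(
            RandomForestRegressor(random_state=self.seed, n_jobs=1),
            self.grid.to_param_grid(),
            scoring="r2",
            cv=cv,
            refit=False,
            n_jobs=1,
        )
        search.fit(self.X, self.y)
        cv_table = cv_table_from_results(search.cv_results_, cv_folds)
        best = select_best_candidate(cv_table)
        estimator = RandomForestRegressor(random_state=self.seed, n_jobs=1, **best).fit(
            self.X, self.y
        )
        return CCSRegressorResults(
            model=self,
            estimator=estimator,
            best_params=best,
            cv_table=cv_table,
            cv_folds=cv_folds,
            target_range=(float(self.y.min()), float(self.y.max())),
        )


@dataclass
class CCSRegressorResults:
    """Fitted CCS forest with its CV record and training-target range."""

    model: CCSRegressor
    estimator: RandomForestRegressor
    best_params: dict[str, int]
    cv_table: pd.DataFrame
    cv_folds: int
    target_range: tuple[float, float]

    @property
    def scope(self) -> str:
        return self.model.scope

    @property
    def best_cv_score(self) -> float:
        return float(self.cv_table["mean_cv_score"].max())

    def predict(self, X) -> np.ndarray:
        """Predict CCS; asserts the forest-averaging range bound."""
        pred = self.estimator.predict(_as_matrix(X))
        lo, hi = self.target_range
        if pred.size and (pred.min() < lo - 1e-6 or pred.max() > hi + 1e-6):
            raise AssertionError(
                f"prediction outside training-target range [{lo}, {hi}]"
            )
        return pred

    def evaluate(
        self,
        X_test,
        y_test: Sequence[float],
        within_thresholds: Sequence[float] = DEFAULT_WITHIN_THRESHOLDS,
    ) -> RegressionReport:
        return evaluate_predictions(y_test, self.predict(X_test), within_thresholds)

    def summary(self) -> str:
        lines = [
            f"CCS random forest regressor (scope: {self.scope})",
            "=" * 40,
            f"n_samples:        {self.model.X.shape[0]}",
            f"n_features:       {self.model.X.shape[1]}",
            f"target range:     {self.target_range[0]:.1f} – {self.target_range[1]:.1f} Å²",
            f"grid candidates:  {self.model.grid.n_candidates}",
            f"cv folds:         {self.cv_folds}",
            f"best n_estimators:     {self.best_params['n_estimators']}",
            f"best min_samples_leaf: {self.best_params['min_samples_leaf']}",
            f"best mean CV R²:  {self.best_cv_score:.4f}",
            f"seed:             {self.model.seed}",
        ]
        return "\n".join(lines)


def train_regressor(
    X,
    y: Sequence[float],
    grid: HyperparameterGrid = DEFAULT_REGRESSOR_GRID,
    cv_folds: int = 5,
    seed: int = DEFAULT_SEED,
    scope: str = DIRECT,
) -> CCSRegressorResults:
    """Grid-searched CV training of a CCS regressor (functional surface)."""
    return CCSRegressor(X, y, scope=scope, grid=grid, seed=seed).fit(cv_folds=cv_folds)


def evaluate_regressor(
    results: CCSRegressorResults,
    X_test,
    y_test: Sequence[float],
    within_thresholds: Sequence[float] = DEFAULT_WITHIN_THRESHOLDS,
) -> RegressionReport:
    """Evaluate a fitted regressor on held-out CCS values (functional surface)."""
    return results.evaluate(X_test, y_test, within_thresholds)


def predict_class_based(
    classifier: SuperClassClassifierResults,
    per_class_models: Mapping[str, CCSRegressorResults],
    smiles: Sequence[str],
    n_bits: int = N_BITS_DEFAULT,
) -> pd.DataFrame:
    """Class-routed CCS prediction for a list of SMILES.

    Each chemical is fingerprinted, its super class predicted by the
    classifier, and its CCS predicted by that class's regressor.  Unparseable
    SMILES yield a flagged row (``ok=False``); the batch continues.

    Returns a DataFrame with columns
    ``smiles, canonical_smiles, assigned_class, predicted_ccs, model_scope, ok``.
    """
    missing = sorted(set(classifier.classes_) - set(per_class_models))
    if missing:
        raise ValueError(f"no regressor for predicted classes: {missing}")
    rows = []
    parsed = []
    for smi in smiles:
        canonical = canonicalize_smiles(smi)
        if canonical is None:
            rows.append(
                {
                    "smiles": smi,
                    "canonical_smiles": None,
                    "assigned_class": None,
                    "predicted_ccs": np.nan,
                    "model_scope": None,
                    "ok": False,
                }
            )
            continue
        fp = tt_fingerprint(canonical, n_bits=n_bits)
        parsed.append((len(rows), canonical, fp))
        rows.append(None)  # placeholder, filled below
    if parsed:
        X = np.stack([fp.bits for _, _, fp in parsed])
        labels = classifier.predict(X)
        for (pos, canonical, fp), label in zip(parsed, labels):
            pred = float(per_class_models[label].predict(fp.bits[None, :])[0])
            rows[pos] = {
                "smiles": smiles[pos],
                "canonical_smiles": canonical,
                "assigned_class": label,
                "predicted_ccs": pred,
                "model_scope": f"class:{label}",
                "ok": True,
            }
    return pd.DataFrame(
        rows,
        columns=["smiles", "canonical_smiles", "assigned_class", "predicted_ccs", "model_scope", "ok"],
    )
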