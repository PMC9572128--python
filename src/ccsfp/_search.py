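"""Shared hyperparameter-grid bookkeeping for the random-forest models."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def evenly_spaced_ints(lo: int, hi: int, k: int) -> list[int]:
    """``k`` evenly spaced integers from ``lo`` to ``hi`` inclusive (half-up rounding)."""
    if k < 1 or hi < lo:
        raise ValueError("invalid range")
    if k == 1:
        return [int(lo)]
    vals = [int(math.floor(lo + i * (hi - lo) / (k - 1) + 0.5)) for i in range(k)]
    if len(set(vals)) != k:
        raise ValueError(f"range [{lo}, {hi}] too narrow for {k} distinct integers")
    return vals


@dataclass(frozen=True)
class HyperparameterGrid:
    """The search grid over forest size and leaf size."""

    n_estimators_values: tuple[int, ...]
    min_samples_leaf_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.n_estimators_values or not self.min_samples_leaf_values:
            raise ValueError("grid axes must be non-empty")
        if any(v < 1 for v in self.n_estimators_values + self.min_samples_leaf_values):
            raise ValueError("all grid values must be >= 1")
        object.__setattr__(self, "n_estimators_values", tuple(self.n_estimators_values))
        object.__setattr__(
            self, "min_samples_leaf_values", tuple(self.min_samples_leaf_values)
        )

    @property
    def n_candidates(self) -> int:
        return len(self.n_estimators_values) * len(self.min_samples_leaf_values)

    def to_param_grid(self) -> dict[str, list[int]]:
        return {
            "n_estimators": list(self.n_estimators_values),
            "min_samples_leaf": list(self.min_samples_leaf_values),
        }


#: 25 candidates: trees 100-200, leaf size 2-15 (5 x 5, evenly spaced).
DEFAULT_CLASSIFIER_GRID = HyperparameterGrid(
    tuple(evenly_spaced_ints(100, 200, 5)), tuple(evenly_spaced_ints(2, 15, 5))
)

#: 50 candidates: trees 100-500, leaf size 5-20 (10 x 5, evenly spaced).
DEFAULT_REGRESSOR_GRID = HyperparameterGrid(
    tuple(evenly_spaced_ints(100, 500, 10)), tuple(evenly_spaced_ints(5, 20, 5))
)


def cv_table_from_results(cv_results: dict, cv_folds: int) -> pd.DataFrame:
    """Per-candidate CV table from sklearn ``cv_results_``."""
    table = pd.DataFrame(
        {
            "n_estimators": [p["n_estimators"] for p in cv_results["params"]],
            "min_samples_leaf": [p["min_samples_leaf"] for p in cv_results["params"]],
            "mean_cv_score": cv_results["mean_test_score"],
            "std_cv_score": cv_results["std_test_score"],
        }
    )
    for split in range(cv_folds):
        table[f"split{split}_score"] = cv_results[f"split{split}_test_score"]
    return table


def select_best_candidate(cv_table: pd.DataFrame) -> dict[str, int]:
    """Best grid candidate by mean CV score; ties -> fewer trees, then larger leaf."""
    best_score = cv_table["mean_cv_score"].max()
    ties = cv_table[cv_table["mean_cv_score"] == best_score]
    row = ties.sort_values(
        ["n_estimators", "min_samples_leaf"], ascending=[True, False]
    ).iloc[0]
    return {
        "n_estimators": int(row["n_estimators"]),
        "min_samples_leaf": int(row["min_samples_leaf"]),
    }
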