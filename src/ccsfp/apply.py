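"""Applying trained predictors to suspect lists and interpreting the models.

A suspect list (NORMAN SusDat-shaped: one identifier and one SMILES per row)
is screened with both CCS prediction strategies; because suspect chemicals
have no measured CCS, the agreement between the direct and the class-based
prediction — the fraction of chemicals whose two predictions differ by less
than a few tens of Å² — is the available robustness diagnostic.

Model interpretation goes through the fingerprint bits: the forest's
impurity-based feature importances are ranked and each top bit is annotated
with example 4-atom torsion paths, recovered by re-enumerating the torsions of
dataset molecules and matching their hashed bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem

from .classify import SuperClassClassifierResults
from .curate import canonicalize_smiles
from .fingerprints import N_BITS_DEFAULT, tt_fingerprint, tt_fingerprint_with_paths
from .regress import CCSRegressorResults, predict_class_based


@dataclass
class ModelBundle:
    """The trained toolkit: classifier, per-class regressors, direct regressor."""

    classifier: SuperClassClassifierResults
    class_models: dict[str, CCSRegressorResults]
    direct_model: CCSRegressorResults
    n_bits: int = N_BITS_DEFAULT
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def predict_suspect_list(
    bundle: ModelBundle, suspects: pd.DataFrame | str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Predict CCS for every suspect with both strategies.

    ``suspects`` is a DataFrame or CSV path with columns ``id,smiles``.
    Returns ``(direct, class_based, rejects)``: one row per parseable suspect
    in each prediction table (columns
    ``id,canonical_smiles,adduct,assigned_class,predicted_ccs,model_scope``),
    and the unparseable rows with reasons in ``rejects``.
    """
    if not isinstance(suspects, pd.DataFrame):
        suspects = pd.read_csv(suspects, dtype=str)
    missing = [c for c in ("id", "smiles") if c not in suspects.columns]
    if missing:
        raise ValueError(f"suspect list missing required columns: {missing}")

    ids, smiles_list, fps, rejects = [], [], [], []
    for row in suspects.itertuples(index=False):
        canonical = canonicalize_smiles(row.smiles)
        if canonical is None:
            rejects.append({"id": row.id, "smiles": row.smiles, "reason": "unparseable SMILES"})
            continue
        ids.append(row.id)
        smiles_list.append(canonical)
        fps.append(tt_fingerprint(canonical, n_bits=bundle.n_bits))
    rejects_df = pd.DataFrame(rejects, columns=["id", "smiles", "reason"])
    if not ids:
        empty = pd.DataFrame(
            columns=["id", "canonical_smiles", "adduct", "assigned_class", "predicted_ccs", "model_scope"]
        )
        return empty, empty.copy(), rejects_df

    X = np.stack([fp.bits for fp in fps])
    direct_pred = bundle.direct_model.predict(X)
    direct_df = pd.DataFrame(
        {
            "id": ids,
            "canonical_smiles": smiles_list,
            "adduct": "[M+H]+",
            "assigned_class": None,
            "predicted_ccs": direct_pred,
            "model_scope": "direct",
        }
    )
    cb = predict_class_based(bundle.classifier, bundle.class_models, smiles_list, n_bits=bundle.n_bits)
    class_df = pd.DataFrame(
        {
            "id": ids,
            "canonical_smiles": smiles_list,
            "adduct": "[M+H]+",
            "assigned_class": cb["assigned_class"],
            "predicted_ccs": cb["predicted_ccs"],
            "model_scope": cb["model_scope"],
        }
    )
    return direct_df, class_df, rejects_df


@dataclass
class ComparisonReport:
    """Agreement between class-based and direct predictions per chemical."""

    table: pd.DataFrame  # id, direct_ccs, class_based_ccs, difference
    fraction_within: dict[float, float]
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def summary_dict(self) -> dict:
        return {
            "n": int(len(self.table)),
            "fraction_within": {f"{t:g}": v for t, v in self.fraction_within.items()},
            "median_abs_difference": float(self.table["difference"].abs().median()),
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        widths = np.diff(self.hist_edges)
        ax.bar(self.hist_edges[:-1], self.hist_counts, width=widths, align="edge")
        ax.set_xlabel("class-based − direct predicted CCS (Å²)")
        ax.set_ylabel("chemicals")
        return ax


def compare_approaches(
    direct: pd.DataFrame,
    class_based: pd.DataFrame,
    thresholds: Sequence[float] = (25.0,),
    n_bins: int = 60,
) -> ComparisonReport:
    """Per-chemical difference between the two prediction strategies.

    difference = class_based − direct; ``fraction_within[t]`` is the fraction
    of chemicals with |difference| ≤ t Å².  Both inputs must cover exactly the
    same identifiers.
    """
    d_ids, c_ids = set(direct["id"]), set(class_based["id"])
    if d_ids != c_ids:
        diff = sorted(d_ids.symmetric_difference(c_ids))
        raise ValueError(f"prediction sets cover different identifiers: {diff}")
    merged = direct.merge(
        class_based, on="id", suffixes=("_direct", "_class"), validate="one_to_one"
    )
    table = pd.DataFrame(
        {
            "id": merged["id"],
            "direct_ccs": merged["predicted_ccs_direct"].astype(float),
            "class_based_ccs": merged["predicted_ccs_class"].astype(float),
        }
    )
    table["difference"] = table["class_based_ccs"] - table["direct_ccs"]
    counts, edges = np.histogram(table["difference"], bins=n_bins)
    return ComparisonReport(
        table=table,
        fraction_within={
            float(t): float((table["difference"].abs() <= t).mean()) for t in thresholds
        },
        hist_counts=counts,
        hist_edges=edges,
    )


@dataclass(frozen=True)
class TorsionExample:
    """One 4-atom torsion path found in a dataset molecule for a given bit."""

    canonical_smiles: str
    atom_indices: tuple[int, ...]
    atom_types: tuple[str, ...]

    @property
    def path_label(self) -> str:
        return "-".join(self.atom_types)


@dataclass
class ImportanceEntry:
    """One fingerprint bit ranked by forest feature importance."""

    bit: int
    importance: float
    examples: tuple[TorsionExample, ...] = ()


def _atom_descriptor(atom: Chem.Atom) -> str:
    label = atom.GetSymbol()
    if atom.GetIsAromatic():
        label += "(ar)"
    return label


def feature_importance_report(
    results,
    dataset_smiles: Sequence[str],
    top_n: int = 10,
    n_examples: int = 3,
    n_bits: int = N_BITS_DEFAULT,
) -> list[ImportanceEntry]:
    """Rank fingerprint bits by impurity importance, with torsion examples.

    ``results`` is any fitted forest results object (classifier or regressor).
    For each of the ``top_n`` most important bits, up to ``n_examples``
    example torsion paths are collected by re-enumerating the torsions of the
    dataset molecules and matching the bit their hash sets.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    importances = np.asarray(results.estimator.feature_importances_)
    order = np.argsort(importances)[::-1][:top_n]

    examples: dict[int, list[TorsionExample]] = {int(b): [] for b in order}
    wanted = set(examples)
    for smi in dataset_smiles:
        if not wanted:
            break
        canonical = canonicalize_smiles(smi)
        if canonical is None:
            continue
        _, bit_paths = tt_fingerprint_with_paths(canonical, n_bits=n_bits)
        mol = Chem.MolFromSmiles(canonical)
        for bit in list(wanted):
            for path in bit_paths.get(bit, ()):
                examples[bit].append(
                    TorsionExample(
                        canonical_smiles=canonical,
                        atom_indices=path,
                        atom_types=tuple(
                            _atom_descriptor(mol.GetAtomWithIdx(i)) for i in path
                        ),
                    )
                )
                if len(examples[bit]) >= n_examples:
                    wanted.discard(bit)
                    break
    return [
        ImportanceEntry(
            bit=int(b), importance=float(importances[b]), examples=tuple(examples[int(b)])
        )
        for b in order
    ]


def importance_report_dataframe(entries: Sequence[ImportanceEntry]) -> pd.DataFrame:
    rows = [
        {
            "bit": e.bit,
            "importance": e.importance,
            "example_paths": "; ".join(x.path_label for x in e.examples),
            "example_smiles": "; ".join(dict.fromkeys(x.canonical_smiles for x in e.examples)),
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=["bit", "importance", "example_paths", "example_smiles"])
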