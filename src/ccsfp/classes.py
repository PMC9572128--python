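"""Super-class consolidation by fingerprint similarity.

Raw CCS libraries carry dozens of chemical "super class" labels, most with a
handful of members — too sparse to train a classifier on.  Consolidation keeps
the ``k`` most populated classes as references and folds every other original
class into one of them by Tanimoto similarity, under two constraints:

* a minimum similarity threshold (default 0.6) — a chemical only "votes" for a
  reference class if its best match there is at least this similar;
* class cohesion — all members of one original class end up in the same
  retained class (the class-level majority vote of its above-threshold
  members decides), so the original taxonomy is never split.

Original classes in which *no* member reaches the threshold are flagged; a
fallback (nearest reference class ignoring the threshold, or a user-supplied
mapping that stands in for expert manual assignment) resolves the flags.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprints import FingerprintVector, bulk_tanimoto, fingerprint_matrix


class AssignmentMode(str, enum.Enum):
    """How a chemical received its consolidated class label."""

    RETAINED = "RETAINED"      # member of a reference class; label kept
    SIMILARITY = "SIMILARITY"  # voted (best match >= threshold)
    COHESION = "COHESION"      # carried along with its original class
    FLAGGED = "FLAGGED"        # no member of its original class reached the threshold


@dataclass
class LabelledChemical:
    """A fingerprinted chemical with its original and consolidated class."""

    canonical_smiles: str
    fp: FingerprintVector
    original_class: str
    assigned_class: str | None = None
    assignment_mode: AssignmentMode | None = None
    best_similarity: float | None = None
    best_match_class: str | None = None


@dataclass
class ConsolidationResult:
    """Outcome of folding the original classes into ``k`` retained classes."""

    retained_classes: list[str]
    assignments: list[LabelledChemical]
    threshold: float
    class_counts: dict[str, int] = field(default_factory=dict)
    n_flagged: int = 0
    flagged_classes: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "canonical_smiles": c.canonical_smiles,
                "original_class": c.original_class,
                "assigned_class": c.assigned_class,
                "assignment_mode": c.assignment_mode.value if c.assignment_mode else None,
                "best_similarity": c.best_similarity,
            }
            for c in self.assignments
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "canonical_smiles",
                "original_class",
                "assigned_class",
                "assignment_mode",
                "best_similarity",
            ],
        )


def select_reference_classes(
    chemicals: Sequence[LabelledChemical], k: int = 5
) -> list[str]:
    """The ``k`` most populated original classes, largest first.

    Population ties are broken lexicographically by class name so the
    selection is deterministic.
    """
    counts = Counter(c.original_class for c in chemicals)
    if len(counts) < k:
        raise ValueError(f"need at least {k} distinct classes, found {len(counts)}")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ordered[:k]]


def consolidate(
    chemicals: Sequence[LabelledChemical],
    k: int = 5,
    threshold: float = 0.6,
    fallback: str | None = "nearest",
    mapping: Mapping[str, str] | None = None,
) -> ConsolidationResult:
    """Fold all original classes into the ``k`` most populated ones.

    Parameters
    ----------
    chemicals:
        Fingerprinted chemicals with original class labels.
    k:
        Number of reference classes to retain.
    threshold:
        Minimum Tanimoto similarity for a chemical's best match to count as a
        vote; must lie in (0, 1].
    fallback:
        How to resolve original classes with no above-threshold member:
        ``"nearest"`` assigns by majority of best matches ignoring the
        threshold; ``"mapping"`` uses the ``mapping`` argument
        (original class -> retained class), standing in for expert manual
        assignment; ``None`` leaves them flagged with no assigned class.

    Notes
    -----
    Votes are cast per chemical (by the retained class of its most similar
    reference chemical) but resolved per original class, so cohesion holds by
    construction.  Vote ties go to the retained class with more members.
    """
    if not chemicals:
        raise ValueError("no chemicals to consolidate")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if fallback not in (None, "nearest", "mapping"):
        raise ValueError(f"unknown fallback {fallback!r}")
    if fallback == "mapping" and mapping is None:
        raise ValueError("fallback='mapping' requires a mapping")

    retained = select_reference_classes(chemicals, k=k)
    retained_rank = {name: i for i, name in enumerate(retained)}

    ref_fps = [c.fp for c in chemicals if c.original_class in retained_rank]
    ref_classes = np.array(
        [retained_rank[c.original_class] for c in chemicals if c.original_class in retained_rank]
    )
    R = fingerprint_matrix(ref_fps)

    by_class: dict[str, list[LabelledChemical]] = {}
    for c in chemicals:
        by_class.setdefault(c.original_class, []).append(c)

    n_flagged = 0
    flagged_classes: list[str] = []
    for name, members in by_class.items():
        if name in retained_rank:
            for c in members:
                c.assigned_class = name
                c.assignment_mode = AssignmentMode.RETAINED
            continue
        sims = bulk_tanimoto(fingerprint_matrix([c.fp for c in members]), R)
        # per member: best similarity to each retained class, ties to the
        # larger (earlier-ranked) class
        per_class_best = np.full((len(members), len(retained)), -1.0)
        for j in range(len(retained)):
            cols = ref_classes == j
            if cols.any():
                per_class_best[:, j] = sims[:, cols].max(axis=1)
        best_sim = per_class_best.max(axis=1)
        best_cls = per_class_best.argmax(axis=1)  # argmax -> earliest rank on ties
        for c, s, j in zip(members, best_sim, best_cls):
            c.best_similarity = float(s)
            c.best_match_class = retained[int(j)]
        voters = [i for i, s in enumerate(best_sim) if s >= threshold]
        if voters:
            votes = Counter(int(best_cls[i]) for i in voters)
            # majority vote; ties -> retained class with more members (lower rank)
            winner = min(votes, key=lambda j: (-votes[j], j))
            target = retained[winner]
            for i, c in enumerate(members):
                c.assigned_class = target
                c.assignment_mode = (
                    AssignmentMode.SIMILARITY if i in set(voters) else AssignmentMode.COHESION
                )
        else:
            n_flagged += len(members)
            flagged_classes.append(name)
            if fallback is None:
                for c in members:
                    c.assigned_class = None
                    c.assignment_mode = AssignmentMode.FLAGGED
            elif fallback == "mapping":
                if name not in mapping:
                    raise ValueError(f"mapping has no entry for flagged class {name!r}")
                target = mapping[name]
                if target not in retained_rank:
                    raise ValueError(
                        f"mapping sends {name!r} to {target!r}, not a retained class"
                    )
                for c in members:
                    c.assigned_class = target
                    c.assignment_mode = AssignmentMode.COHESION
            else:  # nearest
                votes = Counter(int(j) for j in best_cls)
                winner = min(votes, key=lambda j: (-votes[j], j))
                target = retained[winner]
                for c in members:
                    c.assigned_class = target
                    c.assignment_mode = AssignmentMode.COHESION

    assignments = list(chemicals)
    class_counts = Counter(
        c.assigned_class for c in assignments if c.assigned_class is not None
    )
    return ConsolidationResult(
        retained_classes=retained,
        assignments=assignments,
        threshold=threshold,
        class_counts=dict(class_counts),
        n_flagged=n_flagged,
        flagged_classes=sorted(flagged_classes),
    )
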