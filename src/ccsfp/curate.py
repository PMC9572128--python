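"""Curation of multi-laboratory collision cross section (CCS) libraries.

CCS libraries measured on drift-tube (DTIM) and traveling-wave (TWIM) ion
mobility platforms are shipped as flat CSV tables of
``id,smiles,adduct,ccs,library,platform``.  This module harmonizes them into a
single deduplicated dataset keyed on canonical SMILES and a normalized adduct
label, and quantifies inter-laboratory agreement of replicate measurements by
their relative standard deviation (RSD).

Deduplication removes only *exact* replicates — records identical in
(canonical SMILES, adduct, CCS rounded to the curation precision).  Records of
the same ion with *different* measured CCS values are all retained: they carry
the genuine inter-laboratory measurement spread that the replicate report
summarizes.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; we log rejects ourselves.
RDLogger.DisableLog("rdApp.error")

#: Column order required of input library CSV files.
INPUT_COLUMNS = ("id", "smiles", "adduct", "ccs", "library", "platform")

#: Default number of decimals used when matching exact CCS duplicates (0.1 A^2).
DEFAULT_CCS_PRECISION = 1


class Platform(str, enum.Enum):
    """Ion mobility platform that produced a measurement."""

    DTIM = "DTIM"
    TWIM = "TWIM"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: str | None) -> "Platform":
        if value is None:
            return cls.UNKNOWN
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            return cls.UNKNOWN


class AdductClass(str, enum.Enum):
    """Normalized adduct families retained for CCS modelling."""

    M_PLUS_H = "M_PLUS_H"
    M_MINUS_H = "M_MINUS_H"
    M_RADICAL = "M_RADICAL"
    OTHER = "OTHER"


#: Adducts kept by default: protonated, deprotonated and radical ions.
DEFAULT_ALLOWED_ADDUCTS = frozenset(
    {AdductClass.M_PLUS_H, AdductClass.M_MINUS_H, AdductClass.M_RADICAL}
)

_CANONICAL_ADDUCT_LABEL = {
    AdductClass.M_PLUS_H: "[M+H]+",
    AdductClass.M_MINUS_H: "[M-H]-",
    AdductClass.M_RADICAL: "[M]+.",
}


@dataclass(frozen=True)
class Adduct:
    """A normalized adduct: a family plus, for OTHER, the original label."""

    kind: AdductClass
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind is AdductClass.OTHER and not self.label:
            raise ValueError("OTHER adducts must preserve the original label")

    @property
    def display(self) -> str:
        if self.kind is AdductClass.OTHER:
            return str(self.label)
        return _CANONICAL_ADDUCT_LABEL[self.kind]

    def key(self) -> tuple[str, str | None]:
        return (self.kind.value, self.label if self.kind is AdductClass.OTHER else None)


def normalize_adduct(adduct_raw: str, row: str | None = None) -> Adduct:
    """Map a free-text adduct label onto the normalized adduct vocabulary.

    Handles the common dialects ``[M+H]+``, ``M+H``, ``[M + H]+`` (and the
    Unicode minus variants) for protonated/deprotonated ions, and the radical
    spellings ``[M]+.``, ``[M].``, ``[M]+•``.  Anything else becomes
    :attr:`AdductClass.OTHER` with the original label preserved so the
    downstream adduct filter can remove (and count) it.

    Parameters
    ----------
    adduct_raw:
        Free-text adduct label. Must be non-empty.
    row:
        Optional row identifier used in the error message for empty labels.
    """
    raw = "" if adduct_raw is None else str(adduct_raw)
    if not raw.strip():
        where = f" (row {row})" if row is not None else ""
        raise ValueError(f"empty adduct label{where}")
    t = raw.replace("−", "-").replace("–", "-").replace("‒", "-")
    t = t.replace(" ", "")
    t = t.replace("[", "").replace("]", "").replace("(", "").replace(")", "")
    core = t.rstrip("+-.•").upper()
    if core == "M+H":
        return Adduct(AdductClass.M_PLUS_H)
    if core == "M-H":
        return Adduct(AdductClass.M_MINUS_H)
    if core == "M" and ("." in t or "•" in t):
        return Adduct(AdductClass.M_RADICAL)
    return Adduct(AdductClass.OTHER, label=raw.strip())


def canonicalize_smiles(smiles: str) -> str | None:
    """Return the RDKit canonical SMILES, or None if the input does not parse."""
    if smiles is None or not str(smiles).strip():
        return None
    mol = Chem.MolFromSmiles(str(smiles).strip())
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class RawCCSEntry:
    """One measured CCS value exactly as found in a source library."""

    source_id: str
    smiles: str | None
    adduct_raw: str
    ccs: float
    library: str
    platform: Platform = Platform.UNKNOWN

    def __post_init__(self) -> None:
        if not (self.ccs > 0):
            raise ValueError(
                f"CCS must be positive, got {self.ccs!r} (source_id={self.source_id!r})"
            )
        if not self.library:
            raise ValueError(f"library tag is empty (source_id={self.source_id!r})")


@dataclass(frozen=True)
class CCSRecord:
    """A curated CCS measurement keyed by canonical SMILES and adduct."""

    canonical_smiles: str
    adduct: Adduct
    ccs: float
    library: str
    platform: Platform = Platform.UNKNOWN
    super_class: str | None = None
    source_id: str | None = None
    raw_smiles: str | None = None
    adduct_raw: str | None = None

    def __post_init__(self) -> None:
        if not (self.ccs > 0):
            raise ValueError("CCS must be positive")

    def key(self) -> tuple[str, tuple[str, str | None]]:
        return (self.canonical_smiles, self.adduct.key())


@dataclass(frozen=True)
class ReplicateStats:
    """Replicate agreement for one (canonical SMILES, adduct) ion."""

    canonical_smiles: str
    adduct: Adduct
    n: int
    mean_ccs: float
    sd_ccs: float

    @property
    def rsd_pct(self) -> float:
        return 100.0 * self.sd_ccs / self.mean_ccs


@dataclass
class CuratedDataset:
    """A curated CCS dataset plus the per-stage provenance of its curation."""

    records: list[CCSRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.source_id,
                "smiles": r.raw_smiles if r.raw_smiles is not None else r.canonical_smiles,
                "adduct": r.adduct_raw if r.adduct_raw is not None else r.adduct.display,
                "ccs": r.ccs,
                "library": r.library,
                "platform": r.platform.value,
                "canonical_smiles": r.canonical_smiles,
                "adduct_norm": r.adduct.display,
                "super_class": r.super_class,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "smiles",
                "adduct",
                "ccs",
                "library",
                "platform",
                "canonical_smiles",
                "adduct_norm",
                "super_class",
            ],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_library_csv(path: str | Path, library: str | None = None) -> list[RawCCSEntry]:
    """Read one source library from CSV (columns ``id,smiles,adduct,ccs,library,platform``)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            RawCCSEntry(
                source_id=str(row.id),
                smiles=row.smiles if isinstance(row.smiles, str) else None,
                adduct_raw=str(row.adduct),
                ccs=float(row.ccs),
                library=library or str(row.library),
                platform=Platform.parse(row.platform),
            )
        )
    return entries


def merge_and_deduplicate(
    libraries: Sequence[Sequence[RawCCSEntry]],
    ccs_precision: int = DEFAULT_CCS_PRECISION,
) -> CuratedDataset:
    """Concatenate source libraries and collapse exact duplicate measurements.

    SMILES are canonicalized before any keying.  Two entries are exact
    duplicates when they agree on (canonical SMILES, normalized adduct, CCS
    rounded to ``ccs_precision`` decimals); the record from the earliest
    library in ``libraries`` wins.  Entries sharing an ion key but differing in
    CCS are all retained — they are replicates, not duplicates.  Unparseable
    SMILES are excluded and logged in the provenance, never silently dropped.
    """
    if ccs_precision < 0:
        raise ValueError("ccs_precision must be >= 0")
    seen: dict[tuple, CCSRecord] = {}
    parse_failures: list[dict] = []
    input_counts: dict[str, int] = {}
    collapsed: list[dict] = []
    n_input = 0
    for lib_index, entries in enumerate(libraries):
        for entry in entries:
            n_input += 1
            input_counts[entry.library] = input_counts.get(entry.library, 0) + 1
            canonical = canonicalize_smiles(entry.smiles)
            if canonical is None:
                parse_failures.append(
                    {
                        "library": entry.library,
                        "source_id": entry.source_id,
                        "smiles": entry.smiles,
                    }
                )
                logger.warning(
                    "unparseable SMILES %r (library=%s, source_id=%s) excluded",
                    entry.smiles,
                    entry.library,
                    entry.source_id,
                )
                continue
            adduct = normalize_adduct(entry.adduct_raw, row=entry.source_id)
            dedup_key = (canonical, adduct.key(), round(entry.ccs, ccs_precision))
            if dedup_key in seen:
                collapsed.append(
                    {
                        "library": entry.library,
                        "source_id": entry.source_id,
                        "kept_library": seen[dedup_key].library,
                    }
                )
                continue
            seen[dedup_key] = CCSRecord(
                canonical_smiles=canonical,
                adduct=adduct,
                ccs=entry.ccs,
                library=entry.library,
                platform=entry.platform,
                source_id=entry.source_id,
                raw_smiles=entry.smiles,
                adduct_raw=entry.adduct_raw,
            )
    records = list(seen.values())
    provenance = {
        "input_counts": input_counts,
        "n_input": n_input,
        "parse_failures": parse_failures,
        "n_parse_failures": len(parse_failures),
        "duplicates_collapsed": collapsed,
        "n_duplicates_collapsed": len(collapsed),
        "ccs_precision": ccs_precision,
        "stages": [("merged", n_input), ("deduplicated", len(records))],
    }
    return CuratedDataset(records=records, provenance=provenance)


def filter_adducts(
    dataset: CuratedDataset,
    allowed: frozenset[AdductClass] | set[AdductClass] = DEFAULT_ALLOWED_ADDUCTS,
) -> CuratedDataset:
    """Keep only records whose normalized adduct family is in ``allowed``.

    The fingerprint carries no adduct information, so only the protonated,
    deprotonated and radical ions are modelled by default; sodiated and other
    adducts are removed here (and counted in the provenance).
    """
    allowed = frozenset(allowed)
    kept = [r for r in dataset.records if r.adduct.kind in allowed]
    removed = len(dataset.records) - len(kept)
    provenance = dict(dataset.provenance)
    provenance["adducts_allowed"] = sorted(a.value for a in allowed)
    provenance["n_adducts_removed"] = removed
    provenance["stages"] = list(provenance.get("stages", [])) + [
        ("adduct_filtered", len(kept))
    ]
    return CuratedDataset(records=kept, provenance=provenance)


def replicate_stats(
    dataset: CuratedDataset, flag_threshold_pct: float = 10.0
) -> tuple[list[ReplicateStats], dict]:
    """Summarize inter-laboratory replicate agreement per ion.

    Every (canonical SMILES, adduct) key with at least two retained records
    yields one :class:`ReplicateStats` with the sample (n-1) standard
    deviation of its CCS values.  The summary reports the median RSD over all
    replicate keys and flags every key whose RSD exceeds
    ``flag_threshold_pct`` — the gross inter-laboratory outliers worth manual
    inspection.
    """
    groups: dict[tuple, list[CCSRecord]] = {}
    for record in dataset.records:
        groups.setdefault(record.key(), []).append(record)
    stats: list[ReplicateStats] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1])):
        members = groups[key]
        if len(members) < 2:
            continue
        values = [m.ccs for m in members]
        stats.append(
            ReplicateStats(
                canonical_smiles=members[0].canonical_smiles,
                adduct=members[0].adduct,
                n=len(members),
                mean_ccs=statistics.fmean(values),
                sd_ccs=statistics.stdev(values),
            )
        )
    flagged = [s for s in stats if s.rsd_pct > flag_threshold_pct]
    summary = {
        "n_replicate_keys": len(stats),
        "median_rsd_pct": statistics.median(s.rsd_pct for s in stats) if stats else None,
        "flag_threshold_pct": flag_threshold_pct,
        "flagged": [
            (s.canonical_smiles, s.adduct.display, s.rsd_pct) for s in flagged
        ],
    }
    return stats, summary


def replicate_report_dataframe(
    stats: Iterable[ReplicateStats], flag_threshold_pct: float = 10.0
) -> pd.DataFrame:
    """Replicate report as a table: ``canonical_smiles,adduct,n,mean_ccs,sd_ccs,rsd_pct,flagged``."""
    rows = [
        {
            "canonical_smiles": s.canonical_smiles,
            "adduct": s.adduct.display,
            "n": s.n,
            "mean_ccs": s.mean_ccs,
            "sd_ccs": s.sd_ccs,
            "rsd_pct": s.rsd_pct,
            "flagged": s.rsd_pct > flag_threshold_pct,
        }
        for s in stats
    ]
    return pd.DataFrame(
        rows,
        columns=["canonical_smiles", "adduct", "n", "mean_ccs", "sd_ccs", "rsd_pct", "flagged"],
    )


def lookup_missing_smiles(
    entries: Sequence[RawCCSEntry], cid_to_smiles: Mapping[str, str]
) -> list[RawCCSEntry]:
    """Fill missing SMILES from a local identifier->SMILES lookup table.

    Stands in for remote compound-database retrieval: libraries that ship only
    a compound identifier can be completed from a locally supplied table keyed
    by ``source_id``.  Entries with no match are returned unchanged (they will
    be excluded, and logged, at merge time).
    """
    out = []
    for entry in entries:
        if (entry.smiles is None or not str(entry.smiles).strip()) and entry.source_id in cid_to_smiles:
            out.append(replace(entry, smiles=cid_to_smiles[entry.source_id]))
        else:
            out.append(entry)
    return out
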