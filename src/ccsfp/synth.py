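"""Synthetic CCS fixture generator.

Emulates the *shape* of a merged multi-laboratory CCS library — valid SMILES
spanning several structural families, per-record adduct labels, CCS values
produced by a known structural formula plus Gaussian noise, and a fraction of
inter-laboratory replicate records — so the whole curation/encoding/modelling
stack is exercisable without any download.

The pseudo-CCS of a molecule is

    base = c0 + c1 · (heavy-atom count)^(2/3) + c2 · (ring count)

an area-like scaling of a volume-like quantity: structural, monotone in size,
and spanning roughly the 100–450 Å² range of empirical small-molecule CCS
values with the default parameters (80, 25, −5).  A measured record is
``base · (1 + ε)`` with ε ~ Normal(0, noise_rsd/100), the scale of
inter-laboratory replicate scatter.

The five structural families (heteroatom chains, benzenoids, N-heterocycles,
carboxylic acids, sugar-like polyols) stand in for chemical super classes.
Backbone composition is *keyed to molecular size*: molecules of a given
family and size share characteristic local atom patterns, the way homologous
series in empirical libraries do (long lipid chains carry torsions absent
from small metabolites).  Presence fingerprints discard substructure counts,
so without this property the bit set of a repetitive molecule would say
nothing about how big it is; with it, individual torsion bits are
size-indicative and the structural CCS signal is recoverable from the
fingerprint.  The families are fingerprint-separable by construction, not
chemically realistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

FAMILIES = ("benzenoid", "carboxylic_acid", "chain", "n_heterocycle", "polyol")

DEFAULT_FAMILY_MIX = {name: 1.0 / len(FAMILIES) for name in FAMILIES}

#: Default pseudo-CCS structural parameters (c0, c1, c2).
DEFAULT_CCS_PARAMS = (80.0, 25.0, -5.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic fixture dataset."""

    n_molecules: int = 1000
    family_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    ccs_params: tuple[float, float, float] = DEFAULT_CCS_PARAMS
    noise_rsd_pct: float = 2.0
    replicate_rate: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValueError("family_mix fractions must sum to 1")
        unknown = set(self.family_mix) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.noise_rsd_pct < 0:
            raise ValueError("noise_rsd_pct must be >= 0")
        if not (0 <= self.replicate_rate <= 1):
            raise ValueError("replicate_rate must be in [0, 1]")


def _branch(sub: str) -> str:
    return f"({sub})" if sub else ""


_HETERO = ("O", "N", "S")
_BRANCH_ATOMS = ("C", "O", "N", "F")


def _keyed_chain(rng: np.random.Generator, length: int, salt: int = 0,
                 branches: bool = True) -> str:
    """A chain of ``length`` atoms whose composition is keyed to its length.

    The backbone atom pattern and the number of single-atom branches are
    fixed pseudo-random functions of (length, salt), so molecules of the same
    size share local torsion motifs (and an identical heavy-atom count) while
    different sizes get different motifs; the random branch positions and
    identities provide uniqueness without perturbing the size.
    """
    atoms = []
    for i in range(length):
        v = (length * 31 + i * 7 + salt) % 11
        if v >= 7 and atoms and atoms[-1] == "C" and 0 < i < length - 1:
            atoms.append(_HETERO[v % 3])
        else:
            atoms.append("C")
    decorations = [""] * length
    if branches:
        eligible = [i for i in range(1, length - 1) if atoms[i] == "C"]
        n_branches = min(1 + (length * 13 + salt) % 3, len(eligible))
        if n_branches and eligible:
            for i in rng.choice(eligible, size=n_branches, replace=False):
                decorations[i] = f"({rng.choice(_BRANCH_ATOMS)})"
    return "".join(a + d for a, d in zip(atoms, decorations))


def _gen_chain(rng: np.random.Generator) -> str:
    return _keyed_chain(rng, int(rng.integers(4, 15)), salt=0)


def _gen_carboxylic_acid(rng: np.random.Generator) -> str:
    length = int(rng.integers(2, 12))
    body = _keyed_chain(rng, length, salt=3)
    style = length % 3  # head group keyed to the body size
    if style == 0:
        return f"OC(=O){body}C(=O)O"  # diacid
    if style == 1:
        return f"NC({body})C(=O)O"  # alpha-amino acid-like
    return f"{body}C(=O)O"


def _gen_benzenoid(rng: np.random.Generator) -> str:
    if rng.random() < 0.2:  # fused bicyclic core
        sub = _keyed_chain(rng, int(rng.integers(1, 8)), salt=5)
        return f"c1ccc2cc{_branch(sub)}ccc2c1"
    take = int(rng.integers(1, 10))  # side-chain backbone length
    piece = _keyed_chain(rng, take, salt=7)
    marker = ("", "F", "Cl")[take % 3]  # 0/1-atom ring marker, keyed to size
    slots = rng.choice(5, size=2, replace=False)
    subs = {int(slots[0]): piece}
    if marker:
        subs[int(slots[1])] = marker
    parts = ["c1", _branch(subs.get(0, ""))]
    for i in range(1, 5):
        parts.append("c" + _branch(subs.get(i, "")))
    parts.append("c1")
    return "".join(parts)


def _gen_n_heterocycle(rng: np.random.Generator) -> str:
    a = _keyed_chain(rng, int(rng.integers(1, 10)), salt=11)
    b = ("", "C", "F")[len(a) % 3]  # 0/1-atom core marker, keyed to size
    core = int(rng.integers(0, 5))
    if core == 0:
        return f"c1cc{_branch(a)}ncc1{b}"
    if core == 1:
        return f"c1cc{_branch(a)}[nH]c1{b}"
    if core == 2:
        return f"c1nc{_branch(a)}nc(c1){b}"
    if core == 3:
        return f"C1CC{_branch(a)}NCC1{b}"
    if core == 4:
        return f"C1COC{_branch(a)}CN1{b}"
    if core == 5:
        return f"c1ccc2[nH]c{_branch(a)}cc2c1{b}"
    if core == 6:
        return f"c1ccc2nc{_branch(a)}ccc2c1{b}"
    if core == 7:
        return f"C1CC{_branch(a)}NC1{b}"
    return f"c1nc{_branch(a)}cnc1{b}"


#: Backbone decorations for open-chain polyols, two heavy atoms each so the
#: molecule's size is fixed by its unit count, not by which units were drawn.
_POLYOL_UNITS = ("C(O)", "C(N)", "C(C)", "C(F)", "C(S)", "C(Cl)")


def _gen_polyol(rng: np.random.Generator) -> str:
    if rng.random() < 0.25:  # pyranose-like ring
        tail = _keyed_chain(rng, int(rng.integers(1, 6)), salt=17)
        return f"OC1OC({tail})C(O)C(O)C1O"
    k = int(rng.integers(1, 8))
    units = [_POLYOL_UNITS[(k * 5 + i * 3) % len(_POLYOL_UNITS)] for i in range(k)]
    n_swaps = 1 if k < 4 else 2  # random decorations for uniqueness
    for pos in rng.choice(k, size=min(n_swaps, k), replace=False):
        units[int(pos)] = str(rng.choice(_POLYOL_UNITS))
    tail = "CO" if k % 2 else "CN"  # keyed to size
    return "OC" + "".join(units) + tail


_FAMILY_GENERATORS = {
    "chain": _gen_chain,
    "benzenoid": _gen_benzenoid,
    "n_heterocycle": _gen_n_heterocycle,
    "carboxylic_acid": _gen_carboxylic_acid,
    "polyol": _gen_polyol,
}


def _family_counts(spec: SyntheticSpec) -> dict[str, int]:
    # largest-remainder apportionment of n_molecules to families
    names = sorted(spec.family_mix)
    base = {c: math.floor(spec.family_mix[c] * spec.n_molecules) for c in names}
    remainder = {c: spec.family_mix[c] * spec.n_molecules - base[c] for c in names}
    extras = spec.n_molecules - sum(base.values())
    for c in sorted(names, key=lambda c: (-remainder[c], c)):
        if extras <= 0:
            break
        base[c] += 1
        extras -= 1
    zero = [c for c in names if spec.family_mix[c] > 0 and base[c] == 0]
    if zero:
        raise ValueError(
            f"families {zero} have positive fractions but zero molecules at n={spec.n_molecules}"
        )
    return base


def generate_molecules(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Generate ``spec.n_molecules`` unique molecules as (canonical SMILES, family).

    Template-based enumeration with seeded random substituents; deterministic
    for a given spec.  Every returned SMILES parses.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _family_counts(spec)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for family in sorted(counts):
        gen = _FAMILY_GENERATORS[family]
        need = counts[family]
        attempts = 0
        while need > 0:
            attempts += 1
            if attempts > 2000 * counts[family]:
                raise RuntimeError(
                    f"could not generate {counts[family]} unique {family} molecules"
                )
            mol = Chem.MolFromSmiles(gen(rng))
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            out.append((canonical, family))
            need -= 1
    return out


def true_ccs(smiles: str, ccs_params: tuple[float, float, float] = DEFAULT_CCS_PARAMS) -> float:
    """Noise-free pseudo-CCS: c0 + c1·heavy^(2/3) + c2·rings."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    c0, c1, c2 = ccs_params
    base = c0 + c1 * mol.GetNumHeavyAtoms() ** (2.0 / 3.0) + c2 * rdMolDescriptors.CalcNumRings(mol)
    if base <= 0:
        raise ValueError(f"non-positive pseudo-CCS ({base:.2f}) for {smiles!r} with {ccs_params}")
    return base


def assign_synthetic_ccs(
    smiles: str,
    ccs_params: tuple[float, float, float] = DEFAULT_CCS_PARAMS,
    noise_rsd_pct: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """One noisy measured pseudo-CCS value: base · (1 + ε), ε ~ N(0, rsd/100).

    Truncated below at 1% of the noise-free value so a pathological noise draw
    can never produce a non-positive CCS.
    """
    base = true_ccs(smiles, ccs_params)
    if noise_rsd_pct == 0:
        return base
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_rsd_pct / 100.0)
    return max(base * (1.0 + eps), 0.01 * base)


def make_fixture_dataset(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a curate-shaped record table plus the ground-truth table.

    The record table has the curation input schema
    ``id,smiles,adduct,ccs,library,platform``: every molecule appears once as
    a protonated ion from one of two simulated laboratories, and a
    ``replicate_rate`` fraction reappears from the other laboratory with an
    independent noise draw (inter-laboratory replicates).  The ground truth
    (``canonical_smiles,family,ccs_true``) carries the noise-free CCS.
    """
    molecules = generate_molecules(spec)
    rng = np.random.default_rng([spec.seed, 1])
    labs = (("lab_A", "DTIM"), ("lab_B", "TWIM"))
    records = []
    truth = []
    n = len(molecules)
    n_rep = int(round(spec.replicate_rate * n))
    replicated = set(rng.choice(n, size=n_rep, replace=False)) if n_rep else set()
    for i, (smiles, family) in enumerate(molecules):
        truth.append(
            {"canonical_smiles": smiles, "family": family, "ccs_true": true_ccs(smiles, spec.ccs_params)}
        )
        lab = int(rng.integers(0, 2))
        records.append(
            {
                "id": f"SYN{i:05d}",
                "smiles": smiles,
                "adduct": "[M+H]+",
                "ccs": assign_synthetic_ccs(
                    smiles, spec.ccs_params, spec.noise_rsd_pct, rng=rng
                ),
                "library": labs[lab][0],
                "platform": labs[lab][1],
            }
        )
        if i in replicated:
            other = 1 - lab
            records.append(
                {
                    "id": f"SYN{i:05d}R",
                    "smiles": smiles,
                    "adduct": "[M+H]+",
                    "ccs": assign_synthetic_ccs(
                        smiles, spec.ccs_params, spec.noise_rsd_pct, rng=rng
                    ),
                    "library": labs[other][0],
                    "platform": labs[other][1],
                }
            )
    return (
        pd.DataFrame(records, columns=["id", "smiles", "adduct", "ccs", "library", "platform"]),
        pd.DataFrame(truth, columns=["canonical_smiles", "family", "ccs_true"]),
    )
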