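"""Hashed topological-torsion fingerprints and Tanimoto similarity.

Molecules are encoded as fixed-length binary vectors over hashed topological
torsions: every linear path of four bonded atoms is typed (element, aromatic
context, connectivity) and hashed into ``n_bits`` positions; a bit records the
*presence* of at least one torsion of that type.  The default length of 1024
bits is the feature vector used throughout the classification and CCS
regression models.

Tanimoto similarity over these bit sets, |A∩B| / |A∪B|, is the metric used to
consolidate chemical super classes; :func:`pairwise_similarity_summary`
provides the distribution diagnostics (histogram, fraction of pairs below a
threshold, an optional gamma fit) that motivate the consolidation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

#: Fingerprint length used across all models.
N_BITS_DEFAULT = 1024

_GENERATORS: dict[int, object] = {}


def _generator(n_bits: int):
    # countSimulation off: one bit per distinct torsion type (presence bits).
    if n_bits not in _GENERATORS:
        _GENERATORS[n_bits] = rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            fpSize=n_bits, countSimulation=False
        )
    return _GENERATORS[n_bits]


@dataclass(frozen=True)
class FingerprintVector:
    """A fixed-length binary fingerprint."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.bits))

    @classmethod
    def from_on_bits(cls, on_bits: Iterable[int], n_bits: int = N_BITS_DEFAULT) -> "FingerprintVector":
        arr = np.zeros(n_bits, dtype=np.uint8)
        idx = list(on_bits)
        if idx:
            arr[np.asarray(idx, dtype=int)] = 1
        return cls(arr)

    @classmethod
    def from_bitstring(cls, bitstring: str) -> "FingerprintVector":
        return cls(np.frombuffer(bitstring.encode("ascii"), dtype=np.uint8) - ord("0"))

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintVector):
            return NotImplemented
        return self.n_bits == other.n_bits and bool(np.array_equal(self.bits, other.bits))

    def __hash__(self) -> int:
        return hash((self.n_bits, self.on_bits))


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def tt_fingerprint(smiles: str, n_bits: int = N_BITS_DEFAULT) -> FingerprintVector:
    """Hashed topological-torsion presence fingerprint of one molecule.

    Deterministic for a given canonical SMILES; a molecule without any
    4-atom bonded path (e.g. methane) yields the all-zero vector.

    Raises
    ------
    ValueError
        If the SMILES does not parse.
    """
    mol = _mol_from_smiles(smiles)
    fp = _generator(n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return FingerprintVector(arr)


def tt_fingerprint_with_paths(
    smiles: str, n_bits: int = N_BITS_DEFAULT
) -> tuple[FingerprintVector, dict[int, tuple[tuple[int, ...], ...]]]:
    """Fingerprint plus, per set bit, the 4-atom index paths that hash to it."""
    mol = _mol_from_smiles(smiles)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitPaths()
    fp = _generator(n_bits).GetFingerprint(mol, additionalOutput=ao)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    paths = {int(bit): tuple(tuple(p) for p in ps) for bit, ps in ao.GetBitPaths().items()}
    return FingerprintVector(arr), paths


def fingerprint_matrix(fps: Sequence[FingerprintVector]) -> np.ndarray:
    """Stack fingerprints into an (n_molecules, n_bits) uint8 feature matrix."""
    if not fps:
        raise ValueError("no fingerprints given")
    n_bits = fps[0].n_bits
    if any(fp.n_bits != n_bits for fp in fps):
        raise ValueError("fingerprints have inconsistent lengths")
    return np.stack([fp.bits for fp in fps]).astype(np.uint8)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two fingerprints.

    Both-empty fingerprints return 0 by convention.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return inter / union


def bulk_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tanimoto similarity between every row of A and every row of B.

    Rows are 0/1 bit vectors; the 0/0 convention (both rows empty -> 0)
    matches :func:`tanimoto`.
    """
    A = np.asarray(A, dtype=np.float32)
    B = np.asarray(B, dtype=np.float32)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


@dataclass
class SimilaritySummary:
    """Distribution summary of all unordered pairwise Tanimoto similarities."""

    n_pairs: int
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_below: dict[float, float]
    mean: float
    var: float
    gamma_params: tuple[float, float] | None = None  # (shape, scale)

    def plot(self, ax=None):
        """Histogram of pair similarities with the gamma fit overlaid."""
        import matplotlib.pyplot as plt
        from scipy import stats as sps

        if ax is None:
            _, ax = plt.subplots()
        widths = np.diff(self.bin_edges)
        density = self.counts / (self.n_pairs * widths)
        ax.bar(self.bin_edges[:-1], density, width=widths, align="edge", alpha=0.6)
        if self.gamma_params is not None:
            shape, scale = self.gamma_params
            x = np.linspace(self.bin_edges[0], self.bin_edges[-1], 200)
            ax.plot(x, sps.gamma.pdf(x, shape, scale=scale), "r-", lw=1.5)
        ax.set_xlabel("Tanimoto similarity")
        ax.set_ylabel("density")
        return ax


def pairwise_similarity_summary(
    fps: Sequence[FingerprintVector],
    thresholds: Sequence[float] = (0.6,),
    n_bins: int = 50,
    fit_gamma: bool = True,
    chunk_size: int = 5000,
) -> SimilaritySummary:
    """Summarize the distribution of all unordered pairwise similarities.

    Similarities are accumulated block-wise so the full dense pair matrix is
    only ever materialized for at most ``chunk_size`` molecules at a time.
    The optional gamma parameters are a method-of-moments fit to the
    similarity sample — a diagnostic for threshold choice, nothing downstream
    consumes it.
    """
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints for a pairwise summary")
    X = fingerprint_matrix(fps)
    n = X.shape[0]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    below = {float(t): 0 for t in thresholds}
    total = 0
    s_sum = 0.0
    s_sq = 0.0
    for i0 in range(0, n, chunk_size):
        Ai = X[i0 : i0 + chunk_size]
        for j0 in range(i0, n, chunk_size):
            Bj = X[j0 : j0 + chunk_size]
            sim = bulk_tanimoto(Ai, Bj)
            if i0 == j0:
                iu = np.triu_indices(sim.shape[0], k=1)
                vals = sim[iu]
            else:
                vals = sim.ravel()
            total += vals.size
            s_sum += float(vals.sum())
            s_sq += float((vals**2).sum())
            counts += np.histogram(vals, bins=edges)[0]
            for t in below:
                below[t] += int((vals < t).sum())
    mean = s_sum / total
    var = max(s_sq / total - mean**2, 0.0)
    gamma_params = None
    if fit_gamma and var > 0 and mean > 0:
        gamma_params = (mean**2 / var, var / mean)  # method of moments
    return SimilaritySummary(
        n_pairs=total,
        bin_edges=edges,
        counts=counts,
        fraction_below={t: below[t] / total for t in below},
        mean=mean,
        var=var,
        gamma_params=gamma_params,
    )


def write_fingerprint_csv(
    smiles: Sequence[str], path: str | Path, n_bits: int = N_BITS_DEFAULT, compact: bool = False
) -> pd.DataFrame:
    """Export fingerprints as ``canonical_smiles,bitstring`` (or on-bit index list)."""
    rows = []
    for smi in smiles:
        fp = tt_fingerprint(smi, n_bits=n_bits)
        rows.append(
            {
                "canonical_smiles": Chem.CanonSmiles(smi),
                "bitstring": " ".join(map(str, fp.on_bits)) if compact else fp.to_bitstring(),
            }
        )
    df = pd.DataFrame(rows, columns=["canonical_smiles", "bitstring"])
    df.to_csv(path, index=False)
    return df
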