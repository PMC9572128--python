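"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the implementation: torsion paths
are enumerated by walking the bond adjacency over all atom quadruples, and
Tanimoto similarity is computed with Python set arithmetic.
"""

from __future__ import annotations

from itertools import permutations

from rdkit import Chem


def normalize_torsion_path(path: tuple[int, ...]) -> tuple[int, ...]:
    """Canonical representative of a torsion path.

    Open paths: the lexicographically smaller of the path and its reverse.
    Closed 3-ring walks (first atom = last atom): the minimum over all six
    rotations/reflections of the cycle.
    """
    if path[0] == path[-1]:
        a, b, c = path[:3]
        reps = [
            (a, b, c, a), (b, c, a, b), (c, a, b, c),
            (a, c, b, a), (c, b, a, c), (b, a, c, b),
        ]
        return min(reps)
    return min(path, path[::-1])


def brute_force_torsion_paths(smiles: str) -> set[tuple[int, ...]]:
    """All 4-atom bonded torsion walks, orientation-normalized.

    An open path (i, j, k, l) requires bonds i-j, j-k, k-l over four distinct
    atoms.  In a 3-membered ring the walk closes on its first atom
    (i, j, k, i); one representative is kept per triangle.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    adjacency: dict[int, set[int]] = {a.GetIdx(): set() for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        adjacency[bond.GetBeginAtomIdx()].add(bond.GetEndAtomIdx())
        adjacency[bond.GetEndAtomIdx()].add(bond.GetBeginAtomIdx())
    paths = set()
    for i, j, k in permutations(adjacency, 3):
        if j in adjacency[i] and k in adjacency[j]:
            for l in adjacency[k]:
                if l == j:
                    continue
                if l == i:  # closed walk: 3-membered ring
                    paths.add(normalize_torsion_path((i, j, k, i)))
                elif l not in (i, j):
                    paths.add(normalize_torsion_path((i, j, k, l)))
    return paths


def set_tanimoto(a: set[int], b: set[int]) -> float:
    """Tanimoto over explicit on-bit sets; 0/0 -> 0 by convention."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
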