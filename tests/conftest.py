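"""Shared fixtures: small molecule pools and a medium synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from ccsfp import SyntheticSpec, make_fixture_dataset, tt_fingerprint

# Small molecules (<= 8 heavy atoms) covering chains, rings, heteroatoms,
# branching and aromaticity; used for fingerprint oracle checks.
SMALL_MOLECULES = [
    "C",
    "CC",
    "CCC",
    "CCCC",
    "CCCCC",
    "CCCCCC",
    "CC(C)C",
    "CC(C)CC",
    "CCO",
    "CCCO",
    "CCOC",
    "CCOCC",
    "CCN",
    "CCCN",
    "CCNCC",
    "CCSC",
    "CC(=O)O",
    "CCC(=O)O",
    "NCC(=O)O",
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccncc1",
    "c1cc[nH]c1",
    "C1CCCC1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOC1",
    "C1CC1",
    "C1CCC1",
    "OCC(O)CO",
    "OCC(O)C(O)CO",
    "FC(F)(F)CC",
    "ClCCCl",
]


@pytest.fixture(scope="session")
def small_molecules() -> list[str]:
    return list(SMALL_MOLECULES)


@pytest.fixture(scope="session")
def synthetic_small():
    """A 300-molecule fixture dataset with replicates (seed 7)."""
    spec = SyntheticSpec(n_molecules=300, replicate_rate=0.1, seed=7)
    records, truth = make_fixture_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def synthetic_features(synthetic_small):
    """Fingerprint matrix + labels + targets for the 300-molecule fixture."""
    _, records, truth = synthetic_small
    fps = [tt_fingerprint(s) for s in truth["canonical_smiles"]]
    X = np.stack([fp.bits for fp in fps]).astype(np.uint8)
    return X, truth["family"].to_numpy(), truth["ccs_true"].to_numpy(), fps
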