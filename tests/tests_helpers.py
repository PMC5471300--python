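"""Shared helpers for constructing small synthetic family collections."""

import numpy as np

from coevo.alignment import Alignment, Q
from coevo.ipa import PairedFamilies


def make_census_families(census, L=4, seed=0):
    """Paired families with a prescribed per-organism (N_A, N_B) census
    and random sequence content."""
    rng = np.random.default_rng(seed)
    rowsA, rowsB, orgsA, orgsB = [], [], [], []
    for k, (na, nb) in enumerate(census):
        org = f"org{k}"
        for _ in range(na):
            rowsA.append(rng.integers(0, Q, L))
            orgsA.append(org)
        for _ in range(nb):
            rowsB.append(rng.integers(0, Q, L))
            orgsB.append(org)
    alnA = Alignment(
        np.array(rowsA, dtype=np.int8), [f"A{i}" for i in range(len(rowsA))], orgsA
    )
    alnB = Alignment(
        np.array(rowsB, dtype=np.int8), [f"B{i}" for i in range(len(rowsB))], orgsB
    )
    return PairedFamilies(alnA, alnB)
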