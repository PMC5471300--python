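"""Synthetic data with known ground truth for the whole pipeline.

Real inputs to a co-evolution study are deep MSAs and crystal
structures; neither carries a usable ground truth for testing an
inference stack.  This module generates both from scratch:

* a self-avoiding 3D bead chain whose realized heavy-atom contact map
  is the planted topology;
* a Potts model whose strong couplings sit exactly on the planted
  long-range contacts;
* alignments Gibbs-sampled from that model;
* paired two-family paralog collections across synthetic organisms with
  planted inter-family couplings and a known true matching.

Everything is a pure function of its parameters and the supplied RNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import gibbs_sample
from .alignment import AA_ALPHABET, Alignment, GAP, Q, decode
from .potts import PottsModel, zero_sum_gauge

__all__ = [
    "PlantedTopology",
    "PairedTruth",
    "generate_topology",
    "plant_potts",
    "sample_sequences",
    "generate_paired_families",
    "default_inter_pairs",
    "write_toy_structure",
    "consensus_sequence",
]

#: Study-condition defaults for the two synthetic presets.
MONOMER_PRESET = dict(L=40, n_long_range=60, strength=1.2, n_sequences=6000)
PAIRED_PRESET = dict(
    n_organisms=20, paralog_range=(2, 3), n_inter=20, strength=5.0,
    L_A=20, L_B=20,
)

logger = logging.getLogger(__name__)

STEP_LENGTH = 3.8  # Å, consecutive-bead distance (CA-CA virtual bond)
MIN_BEAD_CLEARANCE = 3.9  # Å, self-avoidance radius for non-adjacent beads
CONTACT_CUTOFF = 8.5  # Å, same heavy-atom contact rule as structural maps


@dataclass
class PlantedTopology:
    """Realized chain topology: coordinates, full contact list, and the
    long-range (|i-j| >= 5) subset on which couplings are planted."""

    L: int
    coordinates: np.ndarray
    contacts: list[tuple[int, int]]
    cutoff: float = CONTACT_CUTOFF

    @property
    def long_range(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.contacts if j - i >= 5]

    def contact_set(self) -> set[tuple[int, int]]:
        return set(self.contacts)


@dataclass
class PairedTruth:
    """Ground truth for a paired-family collection."""

    inter_pairs: list[tuple[int, int]]
    matching: dict[str, list[tuple[int, int]]]
    strength: float


def _chain_contacts(coords: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.nonzero(np.triu(d < cutoff, 1))
    return list(zip(ii.tolist(), jj.tolist()))


def _grow_chain(L: int, rng: np.random.Generator, collapse_bias: float) -> np.ndarray | None:
    """One attempt at a self-avoiding biased random walk of L beads."""
    coords = np.zeros((L, 3))
    for i in range(1, L):
        for _ in range(60):
            step = rng.normal(size=3)
            if i >= 2 and collapse_bias > 0:
                center = coords[:i].mean(axis=0) - coords[i - 1]
                norm = np.linalg.norm(center)
                if norm > 1e-9:
                    step = step + collapse_bias * center / norm * np.linalg.norm(step)
            step *= STEP_LENGTH / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i >= 2:
                clear = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if clear.min() < MIN_BEAD_CLEARANCE:
                    continue
            coords[i] = cand
            break
        else:
            return None
    return coords


def generate_topology(
    L: int,
    n_long_range: int,
    rng: np.random.Generator,
    collapse_bias: float = 0.3,
    max_attempts: int = 2000,
) -> PlantedTopology:
    """Self-avoiding 3D bead chain realizing ``n_long_range`` long-range
    contacts under the 8.5 Å cutoff.

    Chains are grown by rejection sampling with a tunable collapse bias
    (pull toward the current center of mass); candidates are redrawn
    until one realizes at least the requested number of |i-j| >= 5
    contacts (and at most 20% more, so the realized topology stays close
    to the request).  If the attempt budget runs out the best chain
    found is returned with a logged warning.
    """
    if L < 10:
        raise ValueError("chain length must be at least 10")
    hi_target = max(n_long_range + 5, int(1.2 * n_long_range))
    best: tuple[int, np.ndarray] | None = None
    for _ in range(max_attempts):
        coords = _grow_chain(L, rng, collapse_bias)
        if coords is None:
            continue
        contacts = _chain_contacts(coords, CONTACT_CUTOFF)
        n_lr = sum(1 for i, j in contacts if j - i >= 5)
        if best is None or abs(n_lr - n_long_range) < abs(best[0] - n_long_range):
            best = (n_lr, coords)
        if n_long_range <= n_lr <= hi_target:
            return PlantedTopology(L, coords, contacts)
    assert best is not None
    logger.warning(
        "topology target of %d long-range contacts not reached in %d "
        "attempts; returning best realization with %d",
        n_long_range,
        max_attempts,
        best[0],
    )
    return PlantedTopology(L, best[1], _chain_contacts(best[1], CONTACT_CUTOFF))


def plant_potts(
    topology: PlantedTopology,
    strength: float,
    rng: np.random.Generator,
    n_pattern: int = 60,
    pattern: str = "sparse",
) -> PottsModel:
    """Potts model whose couplings sit on the planted long-range contacts.

    Fields are zero.  With ``pattern='sparse'`` each long-range contact
    pair gets +/-``strength`` entries on ``n_pattern`` randomly chosen
    non-gap state pairs; with ``pattern='permutation'`` it gets a
    one-to-one state correspondence (+``strength`` on a random
    permutation of the 20 amino acids), the regime of strongly
    specific co-evolving positions.  Blocks are zero-sum gauged on the
    amino-acid sub-block; all other couplings are zero.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    if pattern not in ("sparse", "permutation"):
        raise ValueError("pattern must be 'sparse' or 'permutation'")
    L, q = topology.L, Q
    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    n_aa = len(AA_ALPHABET)
    for i, j in topology.long_range:
        K = np.zeros((q, q))
        if pattern == "permutation":
            K[np.arange(n_aa), rng.permutation(n_aa)] = strength
        else:
            flat = rng.choice(
                n_aa * n_aa, size=min(n_pattern, n_aa * n_aa), replace=False
            )
            rows, cols = np.unravel_index(flat, (n_aa, n_aa))
            K[rows, cols] = rng.choice([-1.0, 1.0], size=len(flat)) * strength
        block = K[:n_aa, :n_aa]
        block -= block.mean(axis=1, keepdims=True)
        block -= block.mean(axis=0, keepdims=True)
        K[:n_aa, :n_aa] = block
        J[i, j] = K
        J[j, i] = K.T
    return PottsModel(h, J)


def sample_sequences(
    model: PottsModel,
    n: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
    thinning: int = 5,
    q_active: int | None = None,
    id_prefix: str = "synth",
) -> Alignment:
    """Gibbs-sample ``n`` sequences from the model's distribution.

    Single chain, single-site heat-bath updates; ``burn_in`` sweeps are
    discarded and one sequence is kept every ``thinning`` sweeps.
    ``q_active`` restricts sampling to the first states of the alphabet
    (useful for exactly enumerable toy models).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if q_active is None:
        q_active = model.q
    seed = int(rng.integers(0, 2**31 - 1))
    matrix = gibbs_sample(
        np.ascontiguousarray(model.h),
        np.ascontiguousarray(model.J),
        n,
        burn_in,
        thinning,
        seed,
        q_active,
    )
    ids = [f"{id_prefix}_{k}" for k in range(n)]
    return Alignment(matrix, ids)


def consensus_sequence(aln: Alignment) -> str:
    """Most frequent non-gap residue per column (ties to the lower code);
    columns with only gaps fall back to alanine."""
    out = []
    for col in aln.matrix.T:
        counts = np.bincount(col[col != GAP], minlength=GAP)
        out.append(AA_ALPHABET[int(counts.argmax())] if counts.sum() else "A")
    return "".join(out)


def default_inter_pairs(L_A: int = 20, L_B: int = 20, n: int = 20) -> list[tuple[int, int]]:
    """Planted inter-family column pairs used by the paired preset: a
    fixed coprime stride so every pair links distinct columns."""
    return [(k % L_A, (7 * k + k // L_A) % L_B) for k in range(n)]


def _joint_inter_model(
    L_A: int, L_B: int, inter_pairs, strength: float, rng: np.random.Generator,
) -> PottsModel:
    """Joint Potts model over L_A + L_B columns with permutation-pattern
    couplings only on the planted inter-family pairs (no couplings at
    zero strength — the independent-families null)."""
    L = L_A + L_B
    contacts = [(i, L_A + j) for i, j in inter_pairs] if strength > 0 else []
    topo = PlantedTopology(L, np.zeros((L, 3)), contacts)
    if strength == 0:
        return PottsModel(np.zeros((L, Q)), np.zeros((L, L, Q, Q)))
    return plant_potts(topo, strength, rng, pattern="permutation")


def generate_paired_families(
    n_organisms: int,
    paralog_range: tuple[int, int],
    inter_pairs: list[tuple[int, int]],
    strength: float,
    rng: np.random.Generator,
    L_A: int = 20,
    L_B: int = 20,
    burn_in: int = 500,
    thinning: int = 30,
):
    """Two paralog families with planted inter-family couplings.

    ``inter_pairs`` are (column in A, column in B) pairs, 0-based.  True
    interacting pairs are co-sampled jointly from the joint model, so
    their A and B halves carry the planted inter-family correlations;
    decoy paralogs (the excess on the larger side of an organism) are
    halves of independent joint samples, i.e. statistically identical
    marginally but uncorrelated with any resident partner.  Organism
    keys are written into the sequence records; the true matching is
    returned alongside.  ``strength`` 0 gives the independent-families
    null (no inter couplings at all).

    Returns ``(alnA, alnB, truth)``.
    """
    if n_organisms < 2:
        raise ValueError("need at least 2 organisms")
    lo, hi = paralog_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid paralog_range")
    model = _joint_inter_model(L_A, L_B, inter_pairs, strength, rng)
    counts = [
        (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        for _ in range(n_organisms)
    ]
    n_joint = sum(max(a, b) for a, b in counts)
    joint = sample_sequences(
        model, n_joint, rng, burn_in=burn_in, thinning=thinning, id_prefix="joint"
    )
    rowsA, idsA, orgsA = [], [], []
    rowsB, idsB, orgsB = [], [], []
    matching: dict[str, list[tuple[int, int]]] = {}
    cursor = 0
    for k, (nA, nB) in enumerate(counts):
        org = f"org{k:03d}"
        n_true = min(nA, nB)
        matching[org] = []
        for p in range(max(nA, nB)):
            row = joint.matrix[cursor]
            cursor += 1
            if p < nA:
                matching_idx_a = len(rowsA)
                rowsA.append(row[:L_A])
                idsA.append(f"A_{org}_p{p}")
                orgsA.append(org)
            if p < nB:
                matching_idx_b = len(rowsB)
                rowsB.append(row[L_A:])
                idsB.append(f"B_{org}_p{p}")
                orgsB.append(org)
            if p < n_true:
                matching[org].append((matching_idx_a, matching_idx_b))
    alnA = Alignment(np.vstack(rowsA), idsA, orgsA)
    alnB = Alignment(np.vstack(rowsB), idsB, orgsB)
    truth = PairedTruth(list(inter_pairs), matching, strength)
    return alnA, alnB, truth


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_toy_structure(
    coordinates: np.ndarray, path, sequence: str | None = None, chain: str = "A"
) -> None:
    """Write a minimal single-chain PDB file, one CA atom per residue.

    ``sequence`` gives the residue identities (alanine everywhere when
    omitted); residues are numbered 1..L.
    """
    coords = np.asarray(coordinates, dtype=float)
    L = len(coords)
    seq = sequence or "A" * L
    if len(seq) != L:
        raise ValueError("sequence length must match the number of beads")
    with open(path, "w") as fh:
        for i in range(L):
            x, y, z = coords[i]
            res = _THREE[seq[i].upper()]
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {res} {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("TER\nEND\n")
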