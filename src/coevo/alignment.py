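"""Multiple sequence alignment I/O, encoding, filtering and reweighting.

Alignments are stored as integer matrices over a 21-letter alphabet
(20 canonical amino acids plus gap).  Downstream model inference needs
two alignment-level quantities computed here: the alignment length L
and the effective number of sequences ``n_eff`` obtained by
similarity-based reweighting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_ALPHABET",
    "GAP",
    "Q",
    "Alignment",
    "SequenceWeights",
    "encode",
    "decode",
    "read_msa",
    "write_msa",
    "filter_gapped_sequences",
    "compute_weights",
]

#: Canonical amino acids in alphabetical one-letter order; codes 0..19.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Integer code of the gap state.
GAP = 20
#: Alphabet size including the gap state.
Q = 21

_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
# Gap symbols and ambiguous/nonstandard residues all collapse to the gap
# state: Uniprot-derived MSAs routinely contain X/B/Z/U/O and no coupling
# information can be attached to them.
for _c in "-.BZJXUO":
    _CODE[_c] = GAP

_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")


class MsaFormatError(ValueError):
    """Raised for malformed or empty alignment input."""


class EncodingError(ValueError):
    """Raised when a residue character has no defined integer code."""


@dataclass
class Alignment:
    """Integer-encoded MSA with per-sequence identifiers and organism keys.

    Attributes
    ----------
    matrix : (M, L) int8 array with values in [0, 20]; 20 is the gap.
    ids : list of sequence identifiers.
    organisms : list of organism keys ('' when unknown).
    """

    matrix: np.ndarray
    ids: list[str]
    organisms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise MsaFormatError("alignment matrix must be M x L with L >= 1")
        if self.matrix.min(initial=0) < 0 or self.matrix.max(initial=0) > GAP:
            raise MsaFormatError("alignment codes must lie in [0, 20]")
        if len(self.ids) != self.matrix.shape[0]:
            raise MsaFormatError("ids length does not match sequence count")
        if not self.organisms:
            self.organisms = [""] * self.matrix.shape[0]
        if len(self.organisms) != self.matrix.shape[0]:
            raise MsaFormatError("organisms length does not match sequence count")

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def gap_fractions(self) -> np.ndarray:
        """Per-sequence fraction of gap positions."""
        return (self.matrix == GAP).mean(axis=1)

    def subset(self, index) -> "Alignment":
        """New alignment restricted to the given sequence indices (order kept)."""
        index = np.asarray(index)
        return Alignment(
            self.matrix[index],
            [self.ids[i] for i in index],
            [self.organisms[i] for i in index],
        )


@dataclass
class SequenceWeights:
    """Similarity-based sequence weights; ``n_eff`` is their sum."""

    w: np.ndarray
    n_eff: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


def encode(residues: str) -> np.ndarray:
    """Encode a residue string into integer codes.

    The 20 canonical amino acids get distinct codes 0..19; '-' and '.'
    as well as ambiguous letters (B, Z, J, X, U, O) map to the gap code;
    lowercase is folded to uppercase.
    """
    out = np.empty(len(residues), dtype=np.int8)
    for pos, ch in enumerate(residues):
        code = _CODE.get(ch.upper())
        if code is None:
            raise EncodingError(
                f"unknown residue character {ch!r} at position {pos + 1}"
            )
        out[pos] = code
    return out


def decode(codes, gap_char: str = "-") -> str:
    """Inverse of :func:`encode` (gap and ambiguous codes all print as gap)."""
    table = AA_ALPHABET + gap_char
    return "".join(table[int(c)] for c in codes)


def extract_organism(description: str) -> str:
    """Organism key from a sequence header.

    Uses the Uniprot ``OS=`` tag when present, else the token after the
    second ``|`` of a ``db|acc|name`` style id, else ''.
    """
    m = _OS_RE.search(description)
    if m:
        return m.group(1).strip()
    head = description.split()[0] if description.split() else ""
    parts = head.split("|")
    if len(parts) >= 3 and parts[2]:
        return parts[2]
    return ""


def read_msa(path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Organism keys come from Stockholm ``#=GS .. OS`` annotations or from
    FASTA description lines (``OS=`` tag / Uniprot-style id).
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise MsaFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(msa) == 0:
        raise MsaFormatError(f"no sequences in {path}")
    rows, ids, organisms = [], [], []
    for rec in msa:
        rows.append(encode(str(rec.seq)))
        ids.append(rec.id)
        org = rec.annotations.get("organism", "")
        if not org:
            org = extract_organism(rec.description or rec.id)
        organisms.append(org)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MsaFormatError(f"sequences in {path} have unequal lengths {lengths}")
    return Alignment(np.vstack(rows), ids, organisms)


def write_msa(aln: Alignment, path, fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Stockholm ('-' for gaps).

    Organism keys are emitted as ``OS=`` description tags (FASTA) or
    ``#=GS .. OS`` lines (Stockholm) so they round-trip through
    :func:`read_msa`.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {fmt!r}")
    records = []
    for i in range(aln.M):
        rec = SeqRecord(Seq(decode(aln.matrix[i])), id=aln.ids[i], description="")
        org = aln.organisms[i]
        if org:
            rec.annotations["organism"] = org
            if fmt == "fasta":
                rec.description = f"OS={org}"
        records.append(rec)
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def filter_gapped_sequences(aln: Alignment, max_gap_fraction: float = 0.10) -> Alignment:
    """Drop sequences whose gap fraction strictly exceeds ``max_gap_fraction``.

    A sequence at exactly the threshold is kept; order is preserved.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    keep = np.flatnonzero(aln.gap_fractions() <= max_gap_fraction)
    if keep.size == 0:
        raise MsaFormatError("gap filter removed every sequence")
    return aln.subset(keep)


def _pairwise_neighbor_counts(matrix: np.ndarray, min_matches: int) -> np.ndarray:
    """Count, per sequence, how many sequences (incl. itself) share at least
    ``min_matches`` identical columns (gap compared as an ordinary symbol)."""
    from ._kernels import neighbor_counts

    return neighbor_counts(np.ascontiguousarray(matrix), min_matches)


def compute_weights(aln: Alignment, identity_threshold: float = 0.90) -> SequenceWeights:
    """Similarity-based reweighting of the alignment.

    Each sequence gets weight 1/n where n is the number of sequences
    (itself included) whose fractional identity to it is >= the
    threshold.  Identity is counted over all L columns with the gap as a
    21st symbol.  ``n_eff`` is the sum of weights, the effective number
    of non-redundant sequences.
    """
    if aln.M < 1:
        raise ValueError("alignment must contain at least one sequence")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    # identity(s,t) >= thr  <=>  matches >= ceil(thr * L)
    min_matches = int(np.ceil(identity_threshold * aln.L - 1e-9))
    counts = _pairwise_neighbor_counts(aln.matrix, min_matches)
    w = 1.0 / counts
    return SequenceWeights(w, float(w.sum()))
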