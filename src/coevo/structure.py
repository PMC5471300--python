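"""Structural contact maps and validation of predicted contacts.

Two residues are in structural contact when at least one pair of their
heavy atoms lies strictly closer than the cutoff (8.5 Å by default; the
contact topology is robust to moderate changes of this value).  Ranked
co-evolution predictions are validated by the cumulative true-positive
rate and by the shortest-path (SP) length of each predicted pair in the
graph of all structural contacts: native contacts have SP = 1, pairs
mediated through one intermediate residue have SP = 2, and so on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .scoring import ContactPrediction

__all__ = [
    "ResidueRecord",
    "StructureContactMap",
    "ColumnResidueMapping",
    "SPResult",
    "UNREACHABLE",
    "read_structure",
    "contact_map",
    "map_columns",
    "true_positive_rate",
    "shortest_path_classes",
]

logger = logging.getLogger(__name__)

#: Sentinel shortest-path value for pairs in disconnected components.
UNREACHABLE = -1


@dataclass
class ResidueRecord:
    """One residue: chain id, author residue number, one-letter code and
    heavy-atom coordinates (n_atoms x 3, Å)."""

    chain: str
    number: int
    code: str
    coords: np.ndarray


@dataclass
class StructureContactMap:
    residues: list[ResidueRecord]
    adjacency: np.ndarray
    cutoff: float
    chain_pair: tuple[str, str] | None = None

    @property
    def n(self) -> int:
        return len(self.residues)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        return g


@dataclass
class ColumnResidueMapping:
    """Monotone map from alignment columns to residue indices (0-based)."""

    pairs: list[tuple[int, int]]
    coverage: float
    reliable: bool = True
    column_to_residue: dict = field(init=False)

    def __post_init__(self) -> None:
        self.column_to_residue = dict(self.pairs)


@dataclass
class SPResult:
    """Per-prediction shortest-path lengths (UNREACHABLE when the two
    residues lie in different components); parallel to ``pairs``."""

    pairs: list[tuple[int, int]]
    sp: list[int]

    def histogram(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in self.sp:
            out[v] = out.get(v, 0) + 1
        return out


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.one_letter_code.isalpha():
        return info.one_letter_code.upper()
    return "X"


def read_structure(path, fmt: str | None = None, model_index: int = 1) -> list[ResidueRecord]:
    """Read residues with heavy-atom coordinates from a PDB/mmCIF file.

    Hydrogens are dropped, alternate locations resolved to the highest
    occupancy, waters and heteroatoms excluded except selenomethionine
    (kept as methionine).  ``model_index`` is 1-based.
    """
    st = gemmi.read_structure(str(path))
    if fmt is not None and fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    if not 1 <= model_index <= len(st):
        raise IndexError(f"model {model_index} not in structure ({len(st)} models)")
    st.setup_entities()
    model = st[model_index - 1]
    records: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            name = res.name
            is_het = res.het_flag == "H"
            if name in ("HOH", "WAT"):
                continue
            if is_het and name != "MSE":
                continue
            code = "M" if name == "MSE" else _one_letter(name)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in best.values()])
            records.append(ResidueRecord(chain.name, res.seqid.num, code, coords))
    if not records:
        raise ValueError(f"no residues with heavy atoms found in {path}")
    return records


def contact_map(
    residues: list[ResidueRecord],
    cutoff: float = 8.5,
    min_chain_separation: int = 1,
    chain_pair: tuple[str, str] | None = None,
) -> StructureContactMap:
    """Heavy-atom contact map (strict ``distance < cutoff``).

    Intra-chain maps include every pair with sequence separation at
    least ``min_chain_separation`` (1 = all distinct pairs); with
    ``chain_pair`` only contacts between the two named chains are kept.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chain_pair is not None:
        residues = [r for r in residues if r.chain in chain_pair]
        if not residues:
            raise ValueError(f"no residues in chains {chain_pair}")
    n = len(residues)
    atoms = np.concatenate([r.coords for r in residues])
    owner = np.concatenate(
        [np.full(len(r.coords), k) for k, r in enumerate(residues)]
    )
    tree = cKDTree(atoms)
    adj = np.zeros((n, n), dtype=bool)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(atoms[pairs[:, 0]] - atoms[pairs[:, 1]], axis=1)
        close = pairs[d < cutoff]  # KD-tree query is <=; the rule is strict
        ri, rj = owner[close[:, 0]], owner[close[:, 1]]
        keep = ri != rj
        adj[ri[keep], rj[keep]] = True
        adj |= adj.T
    for k, r in enumerate(residues):
        for m in range(k + 1, n):
            s = residues[m]
            if r.chain == s.chain and abs(m - k) < min_chain_separation:
                adj[k, m] = adj[m, k] = False
            if chain_pair is not None and r.chain == s.chain:
                adj[k, m] = adj[m, k] = False
    return StructureContactMap(list(residues), adj, cutoff, chain_pair)


def map_columns(
    aln_consensus: str, structure_sequence: str, min_coverage: float = 0.30
) -> ColumnResidueMapping:
    """Map alignment columns onto structure residues by global alignment.

    Needleman-Wunsch with match +1, mismatch 0, affine gap penalties and
    free end gaps; only aligned (match/mismatch) columns enter the
    mapping.  The mapping is flagged unreliable when the aligned
    fraction of the consensus or the identity over aligned columns falls
    below ``min_coverage``.
    """
    if not aln_consensus or not structure_sequence:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.1
    for attr in ("end_insertion_score", "end_deletion_score"):
        setattr(aligner, attr, 0.0)
    alignment = aligner.align(aln_consensus, structure_sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        pairs.extend(zip(range(t0, t1), range(q0, q1)))
    coverage = len(pairs) / len(aln_consensus)
    matches = sum(aln_consensus[i] == structure_sequence[j] for i, j in pairs)
    identity = matches / len(pairs) if pairs else 0.0
    reliable = coverage >= min_coverage and identity >= min_coverage
    if not reliable:
        logger.warning(
            "column-residue mapping covers %.0f%% of the consensus at "
            "%.0f%% identity; treating it as unreliable",
            100 * coverage,
            100 * identity,
        )
    return ColumnResidueMapping(pairs, coverage, reliable)


def _mapped_pairs(
    prediction: ContactPrediction, mapping: ColumnResidueMapping
) -> tuple[list[tuple[int, int]], int]:
    c2r = mapping.column_to_residue
    mapped, dropped = [], 0
    for i, j, _ in prediction.pairs:
        if i in c2r and j in c2r:
            mapped.append((c2r[i], c2r[j]))
        else:
            dropped += 1
    if dropped:
        logger.info("%d predictions not mappable to the structure", dropped)
    return mapped, dropped


def true_positive_rate(
    prediction: ContactPrediction,
    cmap: StructureContactMap,
    mapping: ColumnResidueMapping,
    top_k: int | None = None,
):
    """Fraction of top-ranked predictions that are native contacts.

    Returns ``(tpr_at_top_k, cumulative_curve)`` where the curve gives,
    at each rank, the number of native hits so far divided by the number
    of (mappable) predictions considered up to that point.  Unmappable
    pairs are excluded from the denominator and counted separately.
    """
    mapped, _ = _mapped_pairs(prediction, mapping)
    if not mapped:
        raise ValueError("no prediction could be mapped onto the structure")
    native = np.array([cmap.adjacency[a, b] for a, b in mapped])
    curve = np.cumsum(native) / np.arange(1, len(native) + 1)
    if top_k is None:
        top_k = len(native)
    elif top_k > len(native):
        logger.info("top_k=%d exceeds %d mapped predictions; using all", top_k, len(native))
        top_k = len(native)
    return float(curve[top_k - 1]), curve


def shortest_path_classes(
    prediction: ContactPrediction,
    cmap: StructureContactMap,
    mapping: ColumnResidueMapping,
) -> SPResult:
    """Shortest-path class of each predicted pair.

    The graph contains every structural contact, including sequence
    neighbors — mediation through the chain is part of what the measure
    captures.  Native predictions get SP = 1.
    """
    mapped, _ = _mapped_pairs(prediction, mapping)
    g = cmap.graph()
    sp: list[int] = []
    for a, b in mapped:
        try:
            sp.append(int(nx.shortest_path_length(g, a, b)))
        except nx.NetworkXNoPath:
            sp.append(UNREACHABLE)
    return SPResult(mapped, sp)
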