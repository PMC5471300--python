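"""Contact scores from a fitted Potts model.

The raw score of a position pair is the Frobenius norm of its zero-sum-
gauged coupling block, by default restricted to the 20 x 20 amino-acid
block so that gap-driven couplings (long gap stretches in the MSA) do
not produce spurious predictions.  The average product correction (APC)
then removes position-specific background; for two concatenated
families the correction is taken asymmetrically, averaging over the two
families separately.  Ranked predictions keep the top N pairs (N = MSA
length by convention) among pairs separated by at least 5 positions
along the chain, or among all inter-family pairs for a partitioned
score matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .alignment import GAP
from .potts import PottsModel

__all__ = [
    "ScoreMatrix",
    "ContactPrediction",
    "frobenius_scores",
    "apc_correct",
    "apc_correct_asymmetric",
    "rank_contacts",
    "normalized_inter_score",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Symmetric L x L pair scores; the diagonal is undefined (NaN).

    ``kind`` is one of ``raw`` (Frobenius norms), ``apc`` (after average
    product correction) or ``normalized`` (inter-family normalized
    score).  ``partition`` is the number of columns belonging to family
    A when the matrix covers two concatenated families.
    """

    S: np.ndarray
    kind: str = "raw"
    partition: int | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        L = self.S.shape[0]
        if self.S.shape != (L, L):
            raise ValueError("score matrix must be square")
        if self.kind not in ("raw", "apc", "normalized"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind == "normalized" and self.partition is None:
            raise ValueError("normalized scores require a partition")
        off = ~np.eye(L, dtype=bool)
        if not np.isfinite(self.S[off]).all():
            raise ValueError("off-diagonal scores must be finite")
        if not np.allclose(self.S[off], self.S.T[off]):
            raise ValueError("score matrix must be symmetric")

    @property
    def L(self) -> int:
        return self.S.shape[0]

    def inter_mask(self) -> np.ndarray:
        """Boolean mask of the upper-triangle inter-family block."""
        if self.partition is None:
            raise ValueError("no partition set")
        mask = np.zeros_like(self.S, dtype=bool)
        mask[: self.partition, self.partition :] = True
        return mask


@dataclass
class ContactPrediction:
    """Ranked pair predictions (0-based column indices, i < j)."""

    pairs: list[tuple[int, int, float]]
    min_separation: int
    retained: int

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def _zero_sum_block(K: np.ndarray) -> np.ndarray:
    return K - K.mean(axis=1, keepdims=True) - K.mean(axis=0, keepdims=True) + K.mean()


def frobenius_scores(
    model: PottsModel, exclude_gap: bool = True, partition: int | None = None
) -> ScoreMatrix:
    """Raw contact scores: gauge-invariant Frobenius norms of couplings.

    With ``exclude_gap`` (default) each coupling block is first
    restricted to the 20 x 20 non-gap sub-block and the zero-sum gauge
    is computed on that sub-block, so couplings carried entirely by gap
    states score exactly zero.
    """
    L, q = model.L, model.q
    sel = [a for a in range(q) if a != GAP] if exclude_gap and q == GAP + 1 else range(q)
    sel = np.asarray(list(sel))
    S = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            K = _zero_sum_block(model.J[i, j][np.ix_(sel, sel)])
            S[i, j] = S[j, i] = float(np.sqrt((K * K).sum()))
    return ScoreMatrix(S, kind="raw", partition=partition)


def _apc_block(S: np.ndarray) -> np.ndarray:
    """Symmetric APC on a square block with undefined diagonal."""
    L = S.shape[0]
    if L < 2:
        return S.copy()
    off = ~np.eye(L, dtype=bool)
    row_means = np.array([S[i, off[i]].mean() for i in range(L)])
    overall = S[off].mean()
    if overall == 0.0:
        if np.any(row_means != 0.0):
            raise ValueError("degenerate score matrix: zero mean, nonzero rows")
        return S.copy()
    out = S - np.outer(row_means, row_means) / overall
    out[~off] = np.nan
    return out


def apc_correct(scores: ScoreMatrix) -> ScoreMatrix:
    """Average product correction: S'_ij = S_ij - S̄_i S̄_j / S̄.

    Row means exclude the diagonal; a constant matrix maps exactly to
    zero.
    """
    if scores.kind != "raw":
        raise ValueError("APC expects raw scores")
    return ScoreMatrix(_apc_block(scores.S), kind="apc", partition=scores.partition)


def apc_correct_asymmetric(scores: ScoreMatrix) -> ScoreMatrix:
    """APC for two concatenated families, averaged per family.

    For an inter-family pair (i in A, j in B) the product term uses the
    mean of row i over B and the mean of column j over A, divided by the
    mean over all A x B pairs.  The two intra-family blocks get the
    ordinary symmetric correction.
    """
    if scores.kind != "raw":
        raise ValueError("APC expects raw scores")
    if scores.partition is None:
        raise ValueError("asymmetric APC requires a partition")
    p, L = scores.partition, scores.L
    out = np.full_like(scores.S, np.nan)
    out[:p, :p] = _apc_block(scores.S[:p, :p])
    out[p:, p:] = _apc_block(scores.S[p:, p:])
    inter = scores.S[:p, p:]
    overall = inter.mean()
    if overall == 0.0:
        if np.any(inter != 0.0):
            raise ValueError("degenerate inter block: zero mean, nonzero entries")
        corr = inter.copy()
    else:
        corr = inter - np.outer(inter.mean(axis=1), inter.mean(axis=0)) / overall
    out[:p, p:] = corr
    out[p:, :p] = corr.T
    return ScoreMatrix(out, kind="apc", partition=p)


def rank_contacts(
    scores: ScoreMatrix,
    min_separation: int = 5,
    top_n: int | None = None,
    top_n_multiplier: float = 1.0,
) -> ContactPrediction:
    """Top-N ranked pair predictions.

    Candidates are pairs with ``j - i >= min_separation`` (intra-chain),
    or every inter-family pair when the matrix is partitioned (no
    separation rule applies across a partition).  ``top_n`` defaults to
    L, the standard retention count; ties are broken by lexicographic
    (i, j) order for reproducibility.
    """
    if scores.kind not in ("apc", "normalized"):
        raise ValueError("rank_contacts expects APC-corrected or normalized scores")
    L = scores.L
    if top_n is None:
        top_n = L
    n_keep = math.floor(top_n * top_n_multiplier)
    if scores.partition is not None:
        p = scores.partition
        cand = [(i, j) for i in range(p) for j in range(p, L)]
    else:
        cand = [
            (i, j)
            for i in range(L)
            for j in range(i + min_separation, L)
        ]
    if n_keep > len(cand):
        logger.warning(
            "requested %d contacts but only %d candidate pairs; truncating",
            n_keep,
            len(cand),
        )
        n_keep = len(cand)
    ranked = sorted(cand, key=lambda ij: (-scores.S[ij[0], ij[1]], ij[0], ij[1]))
    pairs = [(i, j, float(scores.S[i, j])) for i, j in ranked[:n_keep]]
    return ContactPrediction(pairs, min_separation, n_keep)


def normalized_inter_score(
    scores: ScoreMatrix, n: int, n_eff: float
) -> ScoreMatrix:
    """Length/depth-normalized inter-family score.

    S̃_ij = S_ij / ( |min over inter pairs of S| * (1 + N / N_eff) ),
    where N is the MSA length and N_eff the effective sequence count.
    The normalization is a positive scaling, so inter-pair ranking is
    unchanged; it makes the acceptance threshold comparable across
    family pairs.
    """
    if scores.kind != "apc":
        raise ValueError("normalization expects APC-corrected scores")
    if scores.partition is None:
        raise ValueError("normalization requires a partition")
    mask = scores.inter_mask()
    min_inter = scores.S[mask].min()
    if min_inter == 0.0:
        raise ValueError("minimum inter-family score is exactly zero")
    denom = abs(min_inter) * (1.0 + n / n_eff)
    S = scores.S.copy()
    full_mask = mask | mask.T
    S[full_mask] = S[full_mask] / denom
    return ScoreMatrix(S, kind="normalized", partition=scores.partition)
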