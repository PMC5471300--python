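"""Iterative paralog matching (IPA) for inter-family contact prediction.

Co-evolutionary analysis of two interacting protein families needs a
concatenated MSA of interaction partners, but organisms carry multiple
paralogs of each family and the correct pairing is unknown.  IPA
resolves the ambiguity self-consistently: starting from a random
within-organism matching, a mean-field Potts model is fit to the
concatenated MSA, its inter-family couplings score every candidate
paralog pair in every organism, and the top-ranking pairs (a number
that grows by ``n_increment`` per iteration) form the matched MSA of
the next iteration, until all ``n_max`` pairs are matched.  The random
seed is discarded after the first iteration.

Because a single run depends on its random seed, the procedure is
repeated; an inter-family column pair is "accepted" in a run when its
normalized score exceeds the threshold (0.8), and the per-pair
acceptance frequency over runs is the robustness measure reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .alignment import Alignment, compute_weights
from .potts import PottsModel, fit_mean_field, fit_plm, zero_sum_gauge, FitConfig
from .scoring import (
    apc_correct_asymmetric,
    frobenius_scores,
    normalized_inter_score,
)

__all__ = [
    "PairedFamilies",
    "IPAConfig",
    "IPAState",
    "AcceptanceTable",
    "n_max",
    "seed_matching",
    "score_candidate_pairs",
    "ipa_run",
    "acceptance_frequencies",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedFamilies:
    """Two families with a per-organism index of member sequences.

    Organisms with zero members on either side are excluded from the
    index (they can never be matched).
    """

    alnA: Alignment
    alnB: Alignment
    index: dict[str, tuple[list[int], list[int]]] = field(init=False)

    def __post_init__(self) -> None:
        byA: dict[str, list[int]] = {}
        byB: dict[str, list[int]] = {}
        for s, org in enumerate(self.alnA.organisms):
            if org:
                byA.setdefault(org, []).append(s)
        for s, org in enumerate(self.alnB.organisms):
            if org:
                byB.setdefault(org, []).append(s)
        self.index = {
            org: (byA[org], byB[org])
            for org in sorted(set(byA) & set(byB))
        }

    @property
    def L_A(self) -> int:
        return self.alnA.L

    @property
    def L_B(self) -> int:
        return self.alnB.L


@dataclass
class IPAConfig:
    n_increment: int = 6
    n_runs: int = 200
    pseudocount: float = 0.5
    score_threshold: float = 0.8
    rng_seed: int = 0
    identity_threshold: float = 0.90
    match_method: str = "greedy"  # or "exact" (per-organism Hungarian)
    plm_config: FitConfig | None = None

    def __post_init__(self) -> None:
        if self.n_increment < 1 or self.n_runs < 1:
            raise ValueError("n_increment and n_runs must be >= 1")
        if self.match_method not in ("greedy", "exact"):
            raise ValueError("match_method must be 'greedy' or 'exact'")


@dataclass
class IPAState:
    iteration: int
    pairs: list[tuple[int, int, str]]  # (index in A, index in B, organism)
    n_select: int


@dataclass
class AcceptanceTable:
    """Per inter-family column pair (i, j): acceptance count over runs."""

    counts: dict[tuple[int, int], int]
    n_runs: int
    mean_score: dict[tuple[int, int], float] = field(default_factory=dict)

    def frequency(self, pair: tuple[int, int]) -> float:
        return self.counts.get(pair, 0) / self.n_runs

    def ranked(self) -> list[tuple[int, int, float]]:
        items = [(i, j, c / self.n_runs) for (i, j), c in self.counts.items()]
        return sorted(items, key=lambda t: (-t[2], t[0], t[1]))


def n_max(families: PairedFamilies) -> int:
    """Maximum number of matchable pairs: sum over organisms of
    min(N_A, N_B)."""
    return sum(min(len(a), len(b)) for a, b in families.index.values())


def seed_matching(families: PairedFamilies, rng: np.random.Generator) -> IPAState:
    """Uniformly random one-to-one within-organism matching (iteration 0)."""
    pairs: list[tuple[int, int, str]] = []
    for org, (idxA, idxB) in families.index.items():
        k = min(len(idxA), len(idxB))
        permA = rng.permutation(len(idxA))[:k]
        permB = rng.permutation(len(idxB))[:k]
        pairs.extend((idxA[a], idxB[b], org) for a, b in zip(permA, permB))
    return IPAState(0, pairs, 0)


def _concatenate(families: PairedFamilies, pairs) -> Alignment:
    rows = [
        np.concatenate([families.alnA.matrix[a], families.alnB.matrix[b]])
        for a, b, _ in pairs
    ]
    ids = [
        f"{families.alnA.ids[a]}|{families.alnB.ids[b]}" for a, b, _ in pairs
    ]
    orgs = [org for _, _, org in pairs]
    return Alignment(np.vstack(rows), ids, orgs)


def score_candidate_pairs(
    model: PottsModel, families: PairedFamilies
) -> dict[str, np.ndarray]:
    """Inter-family co-evolution score of every candidate paralog pair.

    For organism members a (family A) and b (family B), the score sums
    the zero-sum-gauged inter-family couplings J_ij(a_i, b_j) over all
    column pairs.  Returns, per organism, an (N_A, N_B) score array.
    """
    gauged = zero_sum_gauge(model)
    LA = families.L_A
    LB = families.L_B
    Jinter = gauged.J[:LA, LA:]  # (LA, LB, q, q)
    scores: dict[str, np.ndarray] = {}
    for org, (idxA, idxB) in families.index.items():
        A = families.alnA.matrix[idxA].astype(int)  # (nA, LA)
        B = families.alnB.matrix[idxB].astype(int)  # (nB, LB)
        out = np.zeros((len(idxA), len(idxB)))
        for i in range(LA):
            # gather J[i, j, A[:, i], B[:, j]] summed over j for all pairs
            block = Jinter[i]  # (LB, q, q)
            sel = block[np.arange(LB)[None, :], :, B]  # (nB, LB, q)
            summed = sel.sum(axis=1)  # (nB, q)
            out += summed[:, A[:, i]].T
        scores[org] = out
    return scores


def _select_pairs(
    families: PairedFamilies,
    scores: dict[str, np.ndarray],
    n_select: int,
    method: str,
) -> list[tuple[int, int, str]]:
    """Rank candidate pairs globally and keep the top ``n_select`` under
    the one-to-one-per-organism constraint."""
    candidates: list[tuple[float, str, int, int]] = []
    if method == "exact":
        for org, (idxA, idxB) in families.index.items():
            S = scores[org]
            rows, cols = linear_sum_assignment(-S)
            candidates.extend(
                (float(S[a, b]), org, a, b) for a, b in zip(rows, cols)
            )
    else:
        for org, (idxA, idxB) in families.index.items():
            S = scores[org]
            candidates.extend(
                (float(S[a, b]), org, a, b)
                for a in range(S.shape[0])
                for b in range(S.shape[1])
            )
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    usedA: set[tuple[str, int]] = set()
    usedB: set[tuple[str, int]] = set()
    chosen: list[tuple[int, int, str]] = []
    for s, org, a, b in candidates:
        if (org, a) in usedA or (org, b) in usedB:
            continue
        idxA, idxB = families.index[org]
        chosen.append((idxA[a], idxB[b], org))
        usedA.add((org, a))
        usedB.add((org, b))
        if len(chosen) >= n_select:
            break
    return chosen


def ipa_run(
    families: PairedFamilies,
    config: IPAConfig,
    rng: np.random.Generator,
):
    """One full IPA run.

    Returns ``(matched_alignment, history)`` where the alignment
    concatenates the final ``n_max`` matched pairs and the history lists
    the state at every iteration.
    """
    nmax = n_max(families)
    if nmax < 1:
        raise ValueError("the two families share no organism; nothing to match")
    state = seed_matching(families, rng)
    history = [state]
    n_select = 0
    while True:
        concat = _concatenate(families, state.pairs)
        weights = compute_weights(concat, config.identity_threshold)
        model = fit_mean_field(concat, weights, config.pseudocount)
        scores = score_candidate_pairs(model, families)
        n_select = min(n_select + config.n_increment, nmax)
        pairs = _select_pairs(families, scores, n_select, config.match_method)
        state = IPAState(state.iteration + 1, pairs, n_select)
        history.append(state)
        if n_select >= nmax:
            break
    return _concatenate(families, state.pairs), history


def matching_accuracy(
    state: IPAState, truth_matching: dict[str, list[tuple[int, int]]]
) -> float:
    """Fraction of matched pairs that are true interaction partners."""
    true_pairs = {
        (a, b) for pairs in truth_matching.values() for a, b in pairs
    }
    hits = sum(1 for a, b, _ in state.pairs if (a, b) in true_pairs)
    return hits / len(state.pairs)


def _run_and_score(
    families: PairedFamilies, config: IPAConfig, rng: np.random.Generator
) -> np.ndarray:
    """One IPA run followed by pseudo-likelihood scoring of its final
    matched MSA; returns the normalized (L_A+L_B) x (L_A+L_B) score
    matrix."""
    matched, _ = ipa_run(families, config, rng)
    weights = compute_weights(matched, config.identity_threshold)
    model = fit_plm(matched, weights, config.plm_config or FitConfig())
    raw = frobenius_scores(model, partition=families.L_A)
    apc = apc_correct_asymmetric(raw)
    return normalized_inter_score(apc, matched.L, weights.n_eff).S


def acceptance_frequencies(
    families: PairedFamilies, config: IPAConfig
) -> AcceptanceTable:
    """Acceptance frequency of every inter-family column pair.

    Runs IPA ``n_runs`` times from independent random seedings (child
    seeds spawned from ``rng_seed``), fits pseudo-likelihood DCA on each
    final matched MSA, applies the asymmetric APC and the normalized
    inter-family score, and counts for each column pair how often its
    normalized score exceeds ``score_threshold``.
    """
    LA = families.L_A
    counts: dict[tuple[int, int], int] = {}
    sums: dict[tuple[int, int], float] = {}
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_runs)
    any_accepted = False
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        S = _run_and_score(families, config, rng)
        inter = S[:LA, LA:]
        for i in range(LA):
            for j in range(inter.shape[1]):
                pair = (i, j)
                sums[pair] = sums.get(pair, 0.0) + float(inter[i, j])
                if inter[i, j] > config.score_threshold:
                    counts[pair] = counts.get(pair, 0) + 1
                    any_accepted = True
    if not any_accepted:
        logger.info("no inter-family pair exceeded the acceptance threshold")
    mean_score = {k: v / config.n_runs for k, v in sums.items()}
    return AcceptanceTable(counts, config.n_runs, mean_score)
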