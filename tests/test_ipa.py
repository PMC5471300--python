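"""Iterative paralog matching: census arithmetic, seeding, scoring,
iteration schedule and acceptance bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

import coevo.ipa as ipa_mod
from coevo.alignment import Alignment, Q
from coevo.ipa import (
    AcceptanceTable,
    IPAConfig,
    IPAState,
    PairedFamilies,
    acceptance_frequencies,
    ipa_run,
    n_max,
    score_candidate_pairs,
    seed_matching,
)
from coevo.potts import PottsModel
from coevo.synth import default_inter_pairs, generate_paired_families


def make_families(census, L=4, seed=0):
    """Families with given per-organism (N_A, N_B) and random content."""
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
    alnA = Alignment(np.array(rowsA, dtype=np.int8),
                     [f"A{i}" for i in range(len(rowsA))], orgsA)
    alnB = Alignment(np.array(rowsB, dtype=np.int8),
                     [f"B{i}" for i in range(len(rowsB))], orgsB)
    return PairedFamilies(alnA, alnB)


class TestNMax:
    def test_hand_sum(self):
        fam = make_families([(2, 3), (1, 1), (4, 2)])
        assert n_max(fam) == 2 + 1 + 2

    def test_single_forced_pair(self):
        assert n_max(make_families([(1, 1)])) == 1

    def test_no_shared_organisms_refuses(self):
        alnA = Alignment(np.zeros((1, 3), dtype=np.int8), ["a"], ["orgX"])
        alnB = Alignment(np.zeros((1, 3), dtype=np.int8), ["b"], ["orgY"])
        fam = PairedFamilies(alnA, alnB)
        assert n_max(fam) == 0
        with pytest.raises(ValueError):
            ipa_run(fam, IPAConfig(n_runs=1), np.random.default_rng(0))


class TestSeedMatching:
    def test_forced_single_pair(self):
        fam = make_families([(1, 1)])
        state = seed_matching(fam, np.random.default_rng(0))
        assert state.pairs == [(0, 0, "org0")]

    def test_deterministic_under_fixed_seed(self):
        fam = make_families([(3, 3), (2, 2)])
        s1 = seed_matching(fam, np.random.default_rng(5))
        s2 = seed_matching(fam, np.random.default_rng(5))
        assert s1.pairs == s2.pairs

    def test_uniform_over_permutations(self):
        # 3x3 organism: all 6 bijections of the 3 matched slots appear
        # uniformly over repeated seedings (chi-square on 1200 draws)
        fam = make_families([(3, 3)])
        counts: dict[tuple, int] = {}
        for s in range(1200):
            st = seed_matching(fam, np.random.default_rng(s))
            key = tuple(sorted((a, b) for a, b, _ in st.pairs))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        _, p = chisquare(list(counts.values()))
        assert p > 1e-3


class TestScoring:
    def test_zero_couplings_score_zero(self):
        fam = make_families([(2, 2)])
        L = fam.L_A + fam.L_B
        model = PottsModel(np.zeros((L, Q)), np.zeros((L, L, Q, Q)))
        scores = score_candidate_pairs(model, fam)
        assert np.allclose(scores["org0"], 0.0)

    def test_planted_pair_outscores_decoys(self):
        # one strong inter coupling favoring state correspondence; the
        # oracle is exhaustive enumeration of the 2x2 candidate scores
        L_half = 3
        L = 2 * L_half
        J = np.zeros((L, L, Q, Q))
        K = np.zeros((Q, Q))
        K[np.arange(20), np.arange(20)] = 5.0
        J[0, L_half] = K
        J[L_half, 0] = K.T
        model = PottsModel(np.zeros((L, Q)), J)
        matA = np.zeros((2, L_half), dtype=np.int8)
        matB = np.zeros((2, L_half), dtype=np.int8)
        matA[0, 0], matB[0, 0] = 3, 3  # true pair shares state 3
        matA[1, 0], matB[1, 0] = 7, 2  # decoy pair mismatched
        fam = PairedFamilies(
            Alignment(matA, ["a0", "a1"], ["o", "o"]),
            Alignment(matB, ["b0", "b1"], ["o", "o"]),
        )
        S = score_candidate_pairs(model, fam)["o"]
        brute = np.zeros((2, 2))
        from coevo.potts import zero_sum_gauge

        g = zero_sum_gauge(model)
        for a in range(2):
            for b in range(2):
                brute[a, b] = sum(
                    g.J[i, L_half + j, matA[a, i], matB[b, j]]
                    for i in range(L_half)
                    for j in range(L_half)
                )
        assert np.allclose(S, brute)
        assert S[0, 0] > S[0, 1] and S[0, 0] > S[1, 0]

    def test_organism_order_invariance(self):
        fam = make_families([(2, 2), (3, 2)])
        L = fam.L_A + fam.L_B
        rng = np.random.default_rng(1)
        J = rng.normal(size=(L, L, Q, Q)) * 0.1
        J = 0.5 * (J + J.transpose(1, 0, 3, 2))
        for i in range(L):
            J[i, i] = 0
        model = PottsModel(np.zeros((L, Q)), J)
        s1 = score_candidate_pairs(model, fam)
        s2 = score_candidate_pairs(model, fam)
        for org in s1:
            assert np.allclose(s1[org], s2[org])


class TestIpaRun:
    def test_forced_matching_and_schedule(self):
        fam = make_families([(1, 1)] * 13, L=3, seed=2)
        cfg = IPAConfig(n_increment=6, n_runs=1, pseudocount=0.8)
        matched, history = ipa_run(fam, cfg, np.random.default_rng(0))
        assert matched.M == 13
        # n_select grows 6, 12, 18 -> capped at 13
        selects = [s.n_select for s in history[1:]]
        assert selects == [6, 12, 13]

    def test_one_to_one_constraint_every_iteration(self):
        fam = make_families([(3, 3), (2, 3), (3, 2)], L=5, seed=3)
        cfg = IPAConfig(n_increment=2, n_runs=1, pseudocount=0.8)
        matched, history = ipa_run(fam, cfg, np.random.default_rng(1))
        for state in history:
            seenA = [(o, a) for a, _, o in state.pairs]
            seenB = [(o, b) for _, b, o in state.pairs]
            assert len(seenA) == len(set(seenA))
            assert len(seenB) == len(set(seenB))
        assert matched.M == n_max(fam)

    def test_exact_assignment_variant_runs(self):
        fam = make_families([(2, 2), (3, 3)], L=5, seed=4)
        cfg = IPAConfig(n_increment=3, n_runs=1, pseudocount=0.8,
                        match_method="exact")
        matched, _ = ipa_run(fam, cfg, np.random.default_rng(2))
        assert matched.M == n_max(fam)


class TestAcceptance:
    def test_counting_on_mocked_runs(self, monkeypatch):
        # acceptance frequency is pure counting over per-run score grids
        fam = make_families([(1, 1)] * 4, L=2, seed=5)
        grids = iter(
            [
                {(0, 0): 0.9, (0, 1): 0.2},
                {(0, 0): 0.85, (0, 1): 0.9},
                {(0, 0): 0.95, (0, 1): 0.1},
            ]
        )

        def fake_scores(self_fam, config, run_rng):
            grid = next(grids)
            L = 2
            S = np.zeros((2 * L, 2 * L))
            for (i, j), v in grid.items():
                S[i, L + j] = S[L + j, i] = v
            return S

        monkeypatch.setattr(ipa_mod, "_run_and_score", fake_scores)
        table = acceptance_frequencies(fam, IPAConfig(n_runs=3, rng_seed=0))
        assert table.frequency((0, 0)) == pytest.approx(1.0)
        assert table.frequency((0, 1)) == pytest.approx(1 / 3)
        assert table.frequency((1, 1)) == 0.0

    def test_frequencies_bounded(self):
        table = AcceptanceTable({(0, 0): 3, (1, 2): 1}, n_runs=5)
        assert 0.0 <= table.frequency((0, 0)) <= 1.0
        ranked = table.ranked()
        assert ranked[0][:2] == (0, 0)

    def test_deterministic_under_master_seed(self):
        rng = np.random.default_rng(21)
        A, B, _ = generate_paired_families(
            4, (1, 2), default_inter_pairs(8, 8, 6), 5.0, rng, L_A=8, L_B=8
        )
        fam = PairedFamilies(A, B)
        cfg = IPAConfig(n_runs=2, rng_seed=77)
        t1 = acceptance_frequencies(fam, cfg)
        t2 = acceptance_frequencies(fam, cfg)
        assert t1.counts == t2.counts
        assert t1.mean_score == t2.mean_score
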