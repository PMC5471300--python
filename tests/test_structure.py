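"""Structure parsing, contact maps, column mapping, TPR and shortest paths."""

import numpy as np
import pytest

from coevo.scoring import ContactPrediction
from coevo.structure import (
    UNREACHABLE,
    ResidueRecord,
    contact_map,
    map_columns,
    read_structure,
    shortest_path_classes,
    true_positive_rate,
)
from coevo.synth import generate_topology, write_toy_structure


def beads(coords, chain="A"):
    return [
        ResidueRecord(chain, k + 1, "A", np.asarray([c], dtype=float))
        for k, c in enumerate(coords)
    ]


def identity_mapping(n):
    return map_columns("A" * n, "A" * n)


class TestReadStructure:
    def test_round_trip_coordinates(self, tmp_path):
        rng = np.random.default_rng(1)
        topo = generate_topology(15, 5, rng)
        p = tmp_path / "toy.pdb"
        write_toy_structure(topo.coordinates, p)
        res = read_structure(p)
        coords = np.array([r.coords[0] for r in res])
        assert np.abs(coords - topo.coordinates).max() < 1e-3
        assert [r.number for r in res] == list(range(1, 16))

    def test_hydrogens_and_waters_dropped(self, tmp_path):
        p = tmp_path / "h.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  HA  ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        res = read_structure(p)
        assert len(res) == 1
        assert len(res[0].coords) == 1

    def test_multi_model_selection(self, tmp_path):
        lines = ["MODEL        1"]
        lines.append(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C"
        )
        lines += ["ENDMDL", "MODEL        2"]
        lines.append(
            "ATOM      1  CA  ALA A   1      10.000   0.000   0.000  1.00  0.00           C"
        )
        lines += ["ENDMDL", "END"]
        p = tmp_path / "nmr.pdb"
        p.write_text("\n".join(lines) + "\n")
        assert read_structure(p, model_index=1)[0].coords[0, 0] == pytest.approx(0.0)
        assert read_structure(p, model_index=2)[0].coords[0, 0] == pytest.approx(10.0)

    def test_selenomethionine_kept_as_met(self, tmp_path):
        p = tmp_path / "mse.pdb"
        p.write_text(
            "HETATM    1 SE   MSE A   1       0.000   0.000   0.000  1.00  0.00          SE\n"
            "END\n"
        )
        res = read_structure(p)
        assert res[0].code == "M"


class TestContactMap:
    def test_strict_inequality_at_cutoff(self):
        res = beads([(0, 0, 0), (8.5, 0, 0)])
        cm = contact_map(res, cutoff=8.5)
        assert not cm.adjacency[0, 1]

    def test_just_inside_cutoff(self):
        res = beads([(0, 0, 0), (8.499, 0, 0)])
        assert contact_map(res, cutoff=8.5).adjacency[0, 1]

    def test_three_residue_hand_case(self):
        res = beads([(0, 0, 0), (10, 0, 0), (14, 0, 0)])
        cm = contact_map(res, cutoff=8.5)
        contacts = {(i, j) for i, j in zip(*np.nonzero(np.triu(cm.adjacency, 1)))}
        assert contacts == {(1, 2)}

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(2)
        res = beads(rng.uniform(0, 20, size=(12, 3)))
        a_small = contact_map(res, cutoff=6.0).adjacency
        a_big = contact_map(res, cutoff=10.0).adjacency
        assert not np.any(a_small & ~a_big)

    def test_inter_chain_restriction(self):
        res = beads([(0, 0, 0), (3, 0, 0)]) + beads([(1, 0, 0)], chain="B")
        cm = contact_map(res, cutoff=8.5, chain_pair=("A", "B"))
        assert cm.adjacency[0, 2] and cm.adjacency[1, 2]
        assert not cm.adjacency[0, 1]  # same-chain pair excluded

    def test_synthetic_topology_self_consistency(self, tmp_path):
        rng = np.random.default_rng(3)
        topo = generate_topology(20, 12, rng)
        p = tmp_path / "t.pdb"
        write_toy_structure(topo.coordinates, p)
        cm = contact_map(read_structure(p))
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(cm.adjacency, 1)))}
        assert got == set(topo.contacts)


class TestMapColumns:
    def test_identity(self):
        m = map_columns("ACDEFGHIKL", "ACDEFGHIKL")
        assert m.pairs == [(k, k) for k in range(10)]
        assert m.coverage == pytest.approx(1.0)

    def test_n_terminal_truncation_offsets_mapping(self):
        m = map_columns("ACDEFGHIKL", "FGHIKL")
        assert m.pairs == [(k + 4, k) for k in range(6)]
        assert m.coverage == pytest.approx(0.6)

    def test_unrelated_sequences_flagged(self):
        m = map_columns("AAAAAAAAAA", "WWWWWWWWWW")
        assert not m.reliable

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            map_columns("", "ACD")


class TestTPR:
    def _cmap_chain(self, n):
        # linear chain: only sequence neighbors in contact
        coords = [(3.8 * k, 0, 0) for k in range(n)]
        return contact_map(beads(coords), cutoff=8.5, min_chain_separation=1)

    def test_all_native(self):
        cm = self._cmap_chain(6)
        pred = ContactPrediction([(0, 1, 1.0), (1, 2, 0.9)], 0, 2)
        tpr, curve = true_positive_rate(pred, cm, identity_mapping(6))
        assert tpr == 1.0 and np.allclose(curve, 1.0)

    def test_hand_counted_curve(self):
        cm = self._cmap_chain(8)
        # ranks 1 and 3 native (adjacent pairs), 2 and 4 not
        pred = ContactPrediction(
            [(0, 1, 4.0), (0, 5, 3.0), (2, 3, 2.0), (1, 6, 1.0)], 0, 4
        )
        tpr, curve = true_positive_rate(pred, cm, identity_mapping(8))
        assert np.allclose(curve, [1.0, 0.5, 2 / 3, 0.5])
        assert tpr == pytest.approx(0.5)

    def test_top_k_truncation(self):
        cm = self._cmap_chain(6)
        pred = ContactPrediction([(0, 1, 1.0)], 0, 1)
        tpr, _ = true_positive_rate(pred, cm, identity_mapping(6), top_k=10)
        assert tpr == 1.0

    def test_unmappable_pairs_excluded(self):
        cm = self._cmap_chain(6)
        mapping = map_columns("AAAA", "AAAAAA")  # consensus shorter
        pred = ContactPrediction([(0, 1, 1.0), (0, 9, 0.5)], 0, 2)
        tpr, curve = true_positive_rate(pred, cm, mapping)
        assert len(curve) == 1 and tpr == 1.0


class TestShortestPath:
    def test_native_contact_is_sp_one(self):
        coords = [(3.8 * k, 0, 0) for k in range(5)]
        cm = contact_map(beads(coords))
        pred = ContactPrediction([(0, 1, 1.0)], 0, 1)
        sp = shortest_path_classes(pred, cm, identity_mapping(5))
        assert sp.sp == [1]

    def test_mediated_pair_is_sp_two(self):
        coords = [(0, 0, 0), (8, 0, 0), (16, 0, 0)]
        cm = contact_map(beads(coords))
        pred = ContactPrediction([(0, 2, 1.0)], 0, 1)
        sp = shortest_path_classes(pred, cm, identity_mapping(3))
        assert sp.sp == [2]

    def test_disconnected_pair_gets_sentinel(self):
        coords = [(0, 0, 0), (100, 0, 0)]
        cm = contact_map(beads(coords))
        pred = ContactPrediction([(0, 1, 1.0)], 0, 1)
        sp = shortest_path_classes(pred, cmap=cm, mapping=identity_mapping(2))
        assert sp.sp == [UNREACHABLE]

    def test_matches_brute_force_bfs_on_random_toys(self):
        # independent oracle: Floyd-Warshall implemented from scratch
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(8, 50))
            coords = rng.uniform(0, 25, size=(n, 3))
            cm = contact_map(beads(coords), cutoff=9.0)
            dist = np.where(cm.adjacency, 1.0, np.inf)
            np.fill_diagonal(dist, 0.0)
            for k in range(n):
                dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
            pairs = [
                (i, j, 1.0)
                for i in range(n)
                for j in range(i + 1, n)
            ]
            pred = ContactPrediction(pairs, 0, len(pairs))
            sp = shortest_path_classes(pred, cm, identity_mapping(n))
            for (i, j), got in zip(((i, j) for i, j, _ in pairs), sp.sp):
                expect = dist[i, j]
                assert got == (UNREACHABLE if np.isinf(expect) else int(expect))
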