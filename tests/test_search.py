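import numpy as np
import pytest

from sitematch import (
    Selection,
    SearchBudgetError,
    SearchParams,
    build_pseudoatoms,
    find_matches,
    parse_representation,
    seed_pairs,
)
from sitematch.pseudoatoms import MatchUnit, Pseudoatom, PseudoatomSet
from sitematch.synthetic import MotifSpec, _random_rotation, make_structure, plant_motif

from _oracles import brute_force_maxima

SEL = Selection(structure="x", chain_id="A")


def point_set(coords, names=None, independent=False):
    """PseudoatomSet of single-CA units at the given coordinates."""
    units = []
    for i, xyz in enumerate(coords):
        name = (names or ["ALA"] * len(coords))[i]
        ref = ("A", i + 1, "", name)
        units.append(
            MatchUnit(
                unit_id=i,
                residue_ref=ref,
                pseudoatoms=[Pseudoatom(np.asarray(xyz, float), "CA", ref)],
            )
        )
    return PseudoatomSet(units=units, representation="test", independent=independent)


IDENTITY_CA = parse_representation("def * CA\n* *\n")


def to_seed_list(set_a, set_b, rep):
    return [
        (s.unit_a, s.unit_b, s.coords_a, s.coords_b)
        for s in seed_pairs(set_a, set_b, rep)
    ]


class TestSeeds:
    def test_product_of_units_under_wildcard_rule(self):
        a = point_set(np.zeros((3, 3)))
        b = point_set(np.ones((2, 3)))
        assert len(seed_pairs(a, b, IDENTITY_CA)) == 6

    def test_disjoint_alphabets_give_no_seeds(self):
        rep = parse_representation("def ALA CA\ndef VAL CA\nALA\nVAL\n")
        a = point_set(np.zeros((2, 3)), names=["ALA", "ALA"])
        b = point_set(np.ones((2, 3)), names=["VAL", "VAL"])
        assert seed_pairs(a, b, rep) == []

    def test_equivalence_set_seed_enumeration(self):
        rep = parse_representation("def ALA CA\ndef GLY CA\ndef VAL CA\nALA GLY VAL\n")
        a = point_set(np.zeros((2, 3)), names=["ALA", "GLY"])
        b = point_set(np.ones((1, 3)), names=["VAL"])
        assert len(seed_pairs(a, b, rep)) == 2


class TestFindMatches:
    def test_self_comparison_recovers_full_length_at_zero_rmsd(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 15, size=(5, 3))
        s = point_set(pts)
        (m,) = find_matches(s, s, IDENTITY_CA, SearchParams(0.7, min_report_size=1))
        assert m.size_units == 5
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(ia == ib for ia, ib, _ in m.pairs)

    def test_planted_congruent_subset_is_the_unique_maximum(self):
        rng = np.random.default_rng(3)
        motif = rng.uniform(0, 12, size=(4, 3))
        decoys_a = rng.uniform(30, 60, size=(3, 3))
        decoys_b = rng.uniform(-40, -20, size=(3, 3))
        rot = _random_rotation(rng)
        a = np.concatenate([motif, decoys_a])
        b = np.concatenate([motif @ rot.T + 5.0, decoys_b])
        matches = find_matches(
            point_set(a), point_set(b), IDENTITY_CA, SearchParams(0.7, min_report_size=1)
        )
        assert len(matches) == 1
        assert matches[0].size_units == 4
        assert {(ia, ib) for ia, ib, _ in matches[0].pairs} == {(i, i) for i in range(4)}
        assert matches[0].rmsd < 1e-6

    def test_tiny_threshold_leaves_only_single_unit_matches(self):
        rng = np.random.default_rng(8)
        a = point_set(rng.uniform(0, 20, (6, 3)))
        b = point_set(rng.uniform(0, 20, (6, 3)))
        matches = find_matches(a, b, IDENTITY_CA, SearchParams(1e-9, min_report_size=1))
        assert matches and all(m.size_units == 1 for m in matches)

    def test_empty_sets_give_empty_result(self):
        empty = point_set(np.zeros((0, 3)))
        assert find_matches(empty, empty, IDENTITY_CA, SearchParams(0.7)) == []

    def test_min_report_size_suppresses_small_maxima(self):
        a = point_set([[0.0, 0, 0]])
        b = point_set([[0.0, 0, 0]])
        assert find_matches(a, b, IDENTITY_CA, SearchParams(0.7, min_report_size=2)) == []

    def test_node_budget_guard_raises(self):
        rng = np.random.default_rng(0)
        a = point_set(rng.uniform(0, 10, (6, 3)))
        b = point_set(rng.uniform(0, 10, (6, 3)))
        with pytest.raises(SearchBudgetError):
            find_matches(a, b, IDENTITY_CA, SearchParams(5.0, node_budget=10))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 7, size=2)
        a = point_set(rng.uniform(0, 9, (na, 3)))
        b = point_set(rng.uniform(0, 9, (nb, 3)))
        thr = 0.7
        matches = find_matches(a, b, IDENTITY_CA, SearchParams(thr, min_report_size=1))
        seed_list = to_seed_list(a, b, IDENTITY_CA)
        best, maxima = brute_force_maxima(seed_list, thr)
        assert {m.size_units for m in matches} <= {best} and len(matches) == len(maxima)
        got = {
            frozenset((ia, ib) for ia, ib, _ in m.pairs): m.rmsd for m in matches
        }
        want = {
            frozenset((seed_list[i][0], seed_list[i][1]) for i in members): r
            for members, r in maxima
        }
        assert got.keys() == want.keys()
        for k in got:
            assert got[k] == pytest.approx(want[k], abs=1e-8)


class TestInvariances:
    def _random_instance(self, seed, n=8):
        rng = np.random.default_rng(seed)
        return (
            point_set(rng.uniform(0, 14, (n, 3))),
            point_set(rng.uniform(0, 14, (n, 3))),
            rng,
        )

    def test_symmetry_under_argument_swap(self):
        a, b, _ = self._random_instance(5)
        fwd = find_matches(a, b, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        rev = find_matches(b, a, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        assert sorted(m.size_units for m in fwd) == sorted(m.size_units for m in rev)
        fs = {frozenset((ia, ib) for ia, ib, _ in m.pairs) for m in fwd}
        rs = {frozenset((ib, ia) for ia, ib, _ in m.pairs) for m in rev}
        assert fs == rs

    def test_maximum_size_is_monotone_in_threshold(self):
        a, b, _ = self._random_instance(6)
        sizes = []
        for thr in (0.2, 0.5, 0.9, 1.4):
            m = find_matches(a, b, IDENTITY_CA, SearchParams(thr, min_report_size=1))
            sizes.append(m[0].size_units if m else 0)
        assert sizes == sorted(sizes)

    def test_rigid_motion_of_either_input_changes_nothing(self):
        a, b, rng = self._random_instance(7)
        base = find_matches(a, b, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        rot = _random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = point_set([rot @ u.pseudoatoms[0].coords + t for u in b.units])
        after = find_matches(a, moved, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        assert [m.size_units for m in base] == [m.size_units for m in after]
        for m0, m1 in zip(base, after):
            assert m0.rmsd == pytest.approx(m1.rmsd, abs=1e-6)
            assert m0.pairs == m1.pairs

    def test_residue_order_in_input_is_irrelevant(self):
        a, b, rng = self._random_instance(9)
        perm = rng.permutation(len(b.units))
        shuffled = point_set([b.units[i].pseudoatoms[0].coords for i in perm])
        base = find_matches(a, b, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        after = find_matches(a, shuffled, IDENTITY_CA, SearchParams(0.9, min_report_size=1))
        assert sorted(m.size_units for m in base) == sorted(m.size_units for m in after)
        inv = {int(p): i for i, p in enumerate(perm)}
        fs = {frozenset((ia, inv[ib]) for ia, ib, _ in m.pairs) for m in base}
        ss = {frozenset((ia, ib) for ia, ib, _ in m.pairs) for m in after}
        assert fs == ss


class TestGroupedAndIndependentModes:
    def test_grouped_two_point_units_match_jointly(self):
        rep = parse_representation("def SER CA CB\nSER\n")
        rng = np.random.default_rng(4)
        model, _ = make_structure(6, residue_alphabet=("SER",), seed=4)
        pset = build_pseudoatoms(model, SEL, rep)
        (m,) = find_matches(pset, pset, rep, SearchParams(0.7, min_report_size=1))
        assert m.size_units == 6
        assert m.size_pseudoatoms == 12

    def test_independent_mode_lets_one_residue_match_two(self):
        rep = parse_representation("mode independent\ndef SER CA OG\nSER\n")
        # a: one SER whose CA and OG both exist; b: two SERs, each providing
        # only one of the atoms at matching relative geometry
        a = PseudoatomSet(
            units=[
                MatchUnit(0, ("A", 1, "", "SER"), [Pseudoatom(np.array([0.0, 0, 0]), "CA", ("A", 1, "", "SER"))]),
                MatchUnit(1, ("A", 1, "", "SER"), [Pseudoatom(np.array([3.0, 0, 0]), "OG", ("A", 1, "", "SER"))]),
            ],
            representation="t",
            independent=True,
        )
        b = PseudoatomSet(
            units=[
                MatchUnit(0, ("A", 7, "", "SER"), [Pseudoatom(np.array([10.0, 5, 0]), "CA", ("A", 7, "", "SER"))]),
                MatchUnit(1, ("A", 9, "", "SER"), [Pseudoatom(np.array([13.0, 5, 0]), "OG", ("A", 9, "", "SER"))]),
            ],
            representation="t",
            independent=True,
        )
        (m,) = find_matches(a, b, rep, SearchParams(0.2, min_report_size=1))
        assert m.size_units == 2
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        # the two pseudoatoms of residue 1 in a matched different residues in b
        matched_b_residues = {b.units[ib].residue_ref[1] for _, ib, _ in m.pairs}
        assert matched_b_residues == {7, 9}

    def test_independent_mode_respects_atom_types(self):
        rep = parse_representation("mode independent\ndef SER CA OG\nSER\n")
        a = point_set([[0.0, 0, 0]], names=["SER"], independent=True)
        a.units[0].pseudoatoms[0] = Pseudoatom(np.array([0.0, 0, 0]), "CA", ("A", 1, "", "SER"))
        b = point_set([[0.0, 0, 0]], names=["SER"], independent=True)
        b.units[0].pseudoatoms[0] = Pseudoatom(np.array([0.0, 0, 0]), "OG", ("A", 1, "", "SER"))
        assert seed_pairs(a, b, rep) == []


class TestPlantedMotifRecovery:
    def test_noiseless_motif_recovered_exactly(self):
        pm = plant_motif(MotifSpec(k=5, noise_sigma=0.0, decoys=10, seed=21))
        rep = IDENTITY_CA
        pa = build_pseudoatoms(pm.model_a, SEL, rep)
        pb = build_pseudoatoms(pm.model_b, SEL, rep)
        matches = find_matches(pa, pb, rep, SearchParams(0.7, min_report_size=1))
        posA = {u.residue_ref[1]: i for i, u in enumerate(pa.units)}
        posB = {u.residue_ref[1]: i for i, u in enumerate(pb.units)}
        truth = {(posA[a[1]], posB[b[1]]) for a, b in pm.correspondence}
        assert any(truth <= {(ia, ib) for ia, ib, _ in m.pairs} for m in matches)
        best = min(m.rmsd for m in matches)
        assert best < 1e-6

    def test_noisy_motif_recovery_rate(self):
        rep = IDENTITY_CA
        hits = 0
        n_runs = 15
        for seed in range(n_runs):
            pm = plant_motif(MotifSpec(k=8, noise_sigma=0.1, decoys=30, seed=seed))
            pa = build_pseudoatoms(pm.model_a, SEL, rep)
            pb = build_pseudoatoms(pm.model_b, SEL, rep)
            matches = find_matches(pa, pb, rep, SearchParams(0.7))
            posA = {u.residue_ref[1]: i for i, u in enumerate(pa.units)}
            posB = {u.residue_ref[1]: i for i, u in enumerate(pb.units)}
            truth = {(posA[a[1]], posB[b[1]]) for a, b in pm.correspondence}
            if any(truth <= {(ia, ib) for ia, ib, _ in m.pairs} for m in matches):
                hits += 1
        assert hits >= n_runs - 1
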