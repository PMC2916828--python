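import itertools
import math

import numpy as np
import pytest

from sitematch import (
    ScreeningHit,
    Selection,
    SearchParams,
    build_pseudoatoms,
    filter_background,
    hits_to_table,
    proximity_validate,
    roc_auc,
    screen,
)
from sitematch.search import Match
from sitematch.superpose import Superposition
from sitematch.synthetic import MotifSpec, make_ligand_complex, make_structure, plant_motif

from _oracles import kabsch_rmsd

SEL = Selection(structure="x", chain_id="A")


def fake_hit(target_id, size, rmsd, residue_pairs=()):
    sup = Superposition(rotation=np.eye(3), translation=np.zeros(3), rmsd=rmsd)
    match = Match(
        pairs=tuple((i, i, (("CA", "CA"),)) for i in range(size)),
        superposition=sup,
        size_units=size,
        size_pseudoatoms=size,
        residue_pairs=residue_pairs,
    )
    return ScreeningHit(target_id=target_id, match=match)


class TestRocAuc:
    def test_perfect_ranking_scores_one(self):
        assert roc_auc([True, True, False, False]) == pytest.approx(1.0)

    def test_reversed_ranking_scores_zero(self):
        assert roc_auc([False, False, True, True]) == pytest.approx(0.0)

    def test_alternating_example(self):
        # concordant pairs: 3 of 4 -> 0.75
        assert roc_auc([True, False, True, False]) == pytest.approx(0.75)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="undefined AUC"):
            roc_auc([True, True])
        with pytest.raises(ValueError, match="undefined AUC"):
            roc_auc([False])

    def test_matches_concordance_counting_exhaustively(self):
        # brute force: AUC = (concordant + 0.5*tied) / (P*N); with a strict
        # ranking there are no ties, so count pairs (pos before neg)
        for n in range(2, 9):
            for labels in itertools.product([True, False], repeat=n):
                if not (any(labels) and not all(labels)):
                    continue
                pos = [i for i, l in enumerate(labels) if l]
                neg = [i for i, l in enumerate(labels) if not l]
                concordant = sum(1 for p in pos for q in neg if p < q)
                expected = concordant / (len(pos) * len(neg))
                assert roc_auc(list(labels)) == pytest.approx(expected)

    def test_midrank_ties_shared(self):
        # two entries share a rank key; the tied pos/neg pair counts half
        labels = [True, False]
        keys = [(5, 0.1), (5, 0.1)]
        assert roc_auc(labels, rank_keys=keys) == pytest.approx(0.5)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            keys = list(rng.integers(0, 6, n))
            order = np.argsort(keys)
            ranked_labels = labels[order]
            ranked_keys = [keys[i] for i in order]
            ours = roc_auc(list(ranked_labels), rank_keys=ranked_keys)
            theirs = roc_auc_score(labels, [-k for k in keys])
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestFilterBackground:
    def test_strict_less_than_cutoff(self):
        hits = [fake_hit(f"t{i}", s, 0.5) for i, s in enumerate([3, 3, 3, 5, 7])]
        kept = filter_background(hits, min_size=4)
        assert [h.match.size_units for h in kept] == [5, 7]

    def test_min_size_one_keeps_everything(self):
        hits = [fake_hit("a", 1, 0.1), fake_hit("b", 2, 0.2)]
        assert filter_background(hits, 1) == hits

    def test_boundary_sizes_are_retained_in_order(self):
        hits = [fake_hit(f"t{i}", 4, 0.1 * i) for i in range(3)]
        assert filter_background(hits, 4) == hits


class TestProximityValidation:
    def _model_with_ligand(self, distance, element="P"):
        model, _ = make_structure(5, seed=9)
        model = make_ligand_complex(
            model, "PO4", element, [("A", 1)], distance=distance
        )
        first = model.chains["A"][0]
        pairs = ((f"A:{first.name}:1", first.label),)
        hit = fake_hit(model.id, 1, 0.0, residue_pairs=pairs)
        return hit, model, first

    def test_inside_cutoff_validates(self):
        hit, model, first = self._model_with_ligand(4.4)
        ok, dist = proximity_validate(hit, model, element="P", cutoff=4.5)
        assert ok
        assert dist <= 4.4 + 1e-6  # anchor atom sits exactly at the distance

    @pytest.mark.parametrize("distance,expected", [(4.4, True), (4.5, False), (4.6, False)])
    def test_cutoff_is_strict_less_than(self, distance, expected):
        from sitematch.structure import Atom, Residue, StructureModel

        res = Residue(name="GLY", seq_id=1, icode="", chain_id="A",
                      atoms=[Atom("CA", "C", (0.0, 0.0, 0.0))])
        lig = Residue(name="PO4", seq_id=101, icode="", chain_id="A",
                      atoms=[Atom("P", "P", (distance, 0.0, 0.0), is_hetero=True)])
        model = StructureModel(id="m", chains={"A": [res]}, ligands=[lig])
        hit = fake_hit("m", 1, 0.0, (("A:GLY:1", "A:GLY:1"),))
        ok, dist = proximity_validate(hit, model, element="P", cutoff=4.5)
        assert ok is expected
        assert dist == pytest.approx(distance)

    def test_no_ligand_gives_false_and_infinity(self):
        model, _ = make_structure(4, seed=10)
        first = model.chains["A"][0]
        hit = fake_hit(model.id, 1, 0.0, ((f"A:{first.name}:1", first.label),))
        ok, dist = proximity_validate(hit, model, element="P", cutoff=4.5)
        assert not ok
        assert math.isinf(dist)

    def test_element_filter_mismatch_gives_false(self):
        hit, model, first = self._model_with_ligand(4.4, element="MG")
        ok, dist = proximity_validate(hit, model, element="P", cutoff=4.5)
        assert not ok


class TestScreen:
    def _library(self, tmp_path, n_targets=6, planted=2, seed=0):
        """Targets on disk: `planted` carry the probe motif, the rest don't."""
        rep_sel = []
        probe_pm = plant_motif(MotifSpec(k=6, noise_sigma=0.05, decoys=8, seed=seed))
        probe_model = probe_pm.model_a
        paths = []
        for t in range(n_targets):
            if t < planted:
                pm = plant_motif(MotifSpec(k=6, noise_sigma=0.05, decoys=8, seed=seed))
                model = pm.model_b
            else:
                model, _ = make_structure(14, seed=1000 + t)
            from sitematch.structure import model_to_pdb

            p = tmp_path / f"target_{t}.pdb"
            p.write_text(model_to_pdb(model))
            paths.append(str(p))
        return probe_model, paths

    def test_self_hit_ranks_first_with_zero_rmsd(self, tmp_path, coarse_rep):
        model, pdb = make_structure(10, seed=3)
        from sitematch.structure import model_to_pdb

        p = tmp_path / "self.pdb"
        p.write_text(model_to_pdb(model))
        other, _ = make_structure(10, seed=4)
        q = tmp_path / "other.pdb"
        q.write_text(model_to_pdb(other))
        # probe from the written file, so coordinates match the target's
        # PDB-precision values exactly
        from sitematch.structure import read_pdb

        probe = build_pseudoatoms(read_pdb(p), SEL, coarse_rep)
        targets = [
            Selection(structure=str(p), chain_id="A"),
            Selection(structure=str(q), chain_id="A"),
        ]
        hits = screen(probe, targets, coarse_rep, SearchParams(0.7, min_report_size=1))
        assert hits[0].target_id.startswith(str(p))
        assert hits[0].match.size_units == 10
        assert hits[0].match.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_planted_targets_outrank_decoys(self, tmp_path, coarse_rep):
        probe_model, paths = self._library(tmp_path, n_targets=6, planted=2)
        probe = build_pseudoatoms(probe_model, SEL, coarse_rep)
        targets = [Selection(structure=p, chain_id="A") for p in paths]
        hits = screen(probe, targets, coarse_rep, SearchParams(0.7, min_report_size=1))
        top2 = {h.target_id.rsplit("/", 1)[-1].split(":")[0] for h in hits[:2]}
        assert top2 == {"target_0.pdb", "target_1.pdb"}

    def test_result_is_independent_of_target_order(self, tmp_path, coarse_rep):
        probe_model, paths = self._library(tmp_path, n_targets=5, planted=2, seed=7)
        probe = build_pseudoatoms(probe_model, SEL, coarse_rep)
        targets = [Selection(structure=p, chain_id="A") for p in paths]
        fwd = screen(probe, targets, coarse_rep, SearchParams(0.7, min_report_size=1))
        rev = screen(probe, targets[::-1], coarse_rep, SearchParams(0.7, min_report_size=1))
        assert [(h.target_id, h.match.size_units, round(h.match.rmsd, 10)) for h in fwd] == [
            (h.target_id, h.match.size_units, round(h.match.rmsd, 10)) for h in rev
        ]

    def test_unreadable_target_is_skipped_not_fatal(self, tmp_path, coarse_rep, caplog):
        model, _ = make_structure(8, seed=5)
        from sitematch.structure import model_to_pdb

        p = tmp_path / "good.pdb"
        p.write_text(model_to_pdb(model))
        probe = build_pseudoatoms(model, SEL, coarse_rep)
        targets = [
            Selection(structure=str(tmp_path / "missing.pdb"), chain_id="A"),
            Selection(structure=str(p), chain_id="A"),
        ]
        with caplog.at_level("WARNING"):
            hits = screen(probe, targets, coarse_rep, SearchParams(0.7, min_report_size=1))
        assert len(hits) == 1
        assert any("skipped" in r.message for r in caplog.records)

    def test_hit_table_columns(self, tmp_path, coarse_rep):
        model, _ = make_structure(8, seed=5)
        from sitematch.structure import model_to_pdb

        p = tmp_path / "t.pdb"
        p.write_text(model_to_pdb(model))
        probe = build_pseudoatoms(model, SEL, coarse_rep)
        hits = screen(
            probe,
            [Selection(structure=str(p), chain_id="A")],
            coarse_rep,
            SearchParams(0.7, min_report_size=1),
        )
        df = hits_to_table(hits)
        assert list(df.columns) == [
            "target_id",
            "size_units",
            "size_pseudoatoms",
            "rmsd",
            "validated",
            "min_ligand_distance",
            "paired_residues",
        ]
        assert df.iloc[0]["size_units"] == 8
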