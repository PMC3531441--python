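"""Dicer stage: excision/refold, enumeration, the 42 features, assembly."""

import numpy as np
import pytest

from conftest import oracle_dicer_candidates
from mircleave import dicer, drosha
from mircleave.dicer import LENGTH_ONLY_MASK
from mircleave.rna_io import MatureAnnotation
from mircleave.structure import StructureError
from mircleave.synthetic import GenParams, make_perfect_hairpin, plant_hairpin


def prepared(seed=0, signal=0.8, gen_seed=13):
    rec = plant_hairpin(GenParams(seed=gen_seed, signal_strength=signal), seed=seed)
    hp = drosha.prepare(rec)
    return rec, hp


class TestBuildPremirna:
    def test_perfect_hairpin_refolds_to_excised_substructure(self):
        rec = make_perfect_hairpin(30, 8, seed=0, flank_len=20)
        hp = drosha.prepare(rec)
        cand = drosha.enumerate_drosha(hp)[0]
        pm = dicer.build_premirna(hp, cand.cut, refold=True)
        inherited = dicer.build_premirna(hp, cand.cut, refold=False)
        assert pm.structure == inherited.structure
        assert not pm.irregular

    def test_length_bound_enforced(self):
        rec = make_perfect_hairpin(40, 8, seed=1)
        hp = drosha.prepare(rec)
        with pytest.raises(StructureError, match="length"):
            dicer.build_premirna(hp, 1)  # nearly the whole hairpin: > 80 nt

    def test_pairless_excision_is_flagged_irregular(self, monkeypatch):
        rec, hp = prepared(seed=2)
        truth = rec.truth[0]
        import mircleave.dicer as dmod

        monkeypatch.setattr(
            dmod, "fold", lambda s: ("." * len(s), 0.0)
        )  # simulate an excision with no secondary structure
        pm = dicer.build_premirna(hp, truth, refold=True)
        assert pm.irregular and "no_hairpin" in pm.flags[0]
        assert dicer.enumerate_dicer(pm) == []


class TestEnumerate:
    def test_perfect_premirna_has_all_ten_candidates(self):
        # 24-bp arms: every mature length 16..25 stays on the stem
        rec = make_perfect_hairpin(26, 8, seed=3, flank_len=2)
        hp = drosha.prepare(rec)
        cand = drosha.enumerate_drosha(hp)[0]
        pm = dicer.build_premirna(hp, cand.cut, refold=False)
        cuts = [c.cut for c in dicer.enumerate_dicer(pm)]
        assert cuts == oracle_dicer_candidates(pm.structure)
        assert len(cuts) == 10

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_planted_premirnas(self, seed):
        rec, hp = prepared(seed=seed)
        pm = dicer.build_premirna(hp, rec.truth[0], refold=False)
        assert [c.cut for c in dicer.enumerate_dicer(pm)] == (
            oracle_dicer_candidates(pm.structure)
        )

    def test_short_stem_truncates_candidates(self):
        # 18-bp arms: only mature lengths whose cut stays on the stem remain
        rec = make_perfect_hairpin(20, 8, seed=4, flank_len=16)
        hp = drosha.prepare(rec)
        cand = drosha.enumerate_drosha(hp)[-1]
        pm = dicer.build_premirna(hp, cand.cut, refold=False)
        cuts = [c.cut for c in dicer.enumerate_dicer(pm)]
        assert cuts == oracle_dicer_candidates(pm.structure)
        assert 0 < len(cuts) < 10

    def test_planted_truth_among_candidates(self):
        for seed in range(15):
            rec, hp = prepared(seed=seed)
            pm = dicer.build_premirna(hp, rec.truth[0], refold=False)
            local_truth = rec.truth[1] - rec.truth[0]
            assert local_truth in {c.cut for c in dicer.enumerate_dicer(pm)}


class TestFeatures:
    def _pm(self, seed=5):
        rec, hp = prepared(seed=seed)
        return rec, dicer.build_premirna(hp, rec.truth[0], refold=False)

    def test_vector_has_42_entries(self):
        _, pm = self._pm()
        for cand in dicer.enumerate_dicer(pm):
            assert dicer.dicer_features(cand, pm).shape == (42,)

    def test_perfect_stem_region_is_all_zero_structure(self):
        rec = make_perfect_hairpin(26, 8, seed=6, flank_len=2)
        hp = drosha.prepare(rec)
        dc = drosha.enumerate_drosha(hp)[0]
        pm = dicer.build_premirna(hp, dc.cut, refold=False)
        cand = dicer.enumerate_dicer(pm)[0]
        vec = dicer.dicer_features(cand, pm)
        assert (vec[:40] == 0).all()
        assert vec[40] == 1.0  # first paired nucleotide, 1-based
        assert vec[41] == cand.mature_len
        # perfect-stem identity: sum of all features = first_paired + length
        assert vec.sum() == vec[40] + vec[41]

    def test_constructed_loops_are_counted_in_the_grid(self):
        # pre-miRNA-like stem with one 2x3 internal loop and one 1-nt 3' bulge
        import mircleave.synthetic as syn
        from mircleave.structure import parse_dotbracket, select_stemloop

        b = syn._Builder(np.random.default_rng(0))
        for _ in range(8):
            b.add_pair("GC")
        b.add_internal_loop(2, 3)
        for _ in range(6):
            b.add_pair("CG")
        b.add_bulge3(1)
        for _ in range(12):
            b.add_pair("GC")
        rec = syn._assemble(b, loop_seq="AACAA", f5="", f3="", record_id="toy")
        pt = parse_dotbracket(rec.sequence, rec.structure)
        pm = dicer.PreMiRNA(
            sequence=rec.sequence, structure=rec.structure,
            pair_table=pt, path=select_stemloop(pt), offset=0,
        )
        cand = [c for c in dicer.enumerate_dicer(pm) if c.cut == 25][0]
        vec = dicer.dicer_features(cand, pm)
        grid = vec[:36].reshape(6, 6)
        assert grid[1, 2] == 1  # one 2x3 internal loop
        assert grid.sum() == 1
        b5c, b5n, b3c, b3n = vec[36:40]
        assert (b5c, b5n) == (0, 0)
        assert (b3c, b3n) == (1, 1)

    def test_oversized_loop_marks_irregular(self):
        import mircleave.synthetic as syn
        from mircleave.structure import parse_dotbracket, select_stemloop

        b = syn._Builder(np.random.default_rng(1))
        for _ in range(6):
            b.add_pair("GC")
        b.add_internal_loop(7, 2)  # 5' side exceeds the 6-nt limit
        for _ in range(14):
            b.add_pair("CG")
        rec = syn._assemble(b, loop_seq="AACAA", f5="", f3="", record_id="big")
        pt = parse_dotbracket(rec.sequence, rec.structure)
        pm = dicer.PreMiRNA(
            sequence=rec.sequence, structure=rec.structure,
            pair_table=pt, path=select_stemloop(pt), offset=0,
        )
        cand = dicer.enumerate_dicer(pm)[-1]
        with pytest.raises(dicer.IrregularStructure, match="internal loop"):
            dicer.dicer_features(cand, pm)
        clipped = dicer.candidate_matrix(pm, [cand], clip=True)[0]
        assert clipped[:36].reshape(6, 6)[5, 1] == 1  # clipped to 6x2

    def test_grid_ignores_terminal_loop_composition(self):
        rec, hp = prepared(seed=9)
        pm = dicer.build_premirna(hp, rec.truth[0], refold=False)
        cands = dicer.enumerate_dicer(pm)
        X1 = dicer.candidate_matrix(pm, cands)
        # replace the terminal loop sequence: features must not change
        li, lj = pm.path.loop_junction
        seq2 = pm.sequence[: li + 1] + "C" * (lj - li - 1) + pm.sequence[lj:]
        from mircleave.structure import parse_dotbracket

        pm2 = dicer.PreMiRNA(
            sequence=seq2, structure=pm.structure,
            pair_table=parse_dotbracket(seq2, pm.structure),
            path=pm.path, offset=pm.offset,
        )
        X2 = dicer.candidate_matrix(pm2, cands)
        assert np.array_equal(X1, X2)


class TestTruth:
    def test_5p_annotation_maps_directly(self):
        rec, hp = prepared(seed=10)
        pm = dicer.build_premirna(hp, rec.truth[0], refold=False)
        c = dicer.derive_dicer_truth(pm, rec)
        assert c.position == rec.truth[1] - rec.truth[0]

    @pytest.mark.parametrize("seed", range(40))
    def test_3p_only_roundtrip(self, seed):
        rec, hp = prepared(seed=seed)
        pm = dicer.build_premirna(hp, rec.truth[0], refold=False)
        only3 = rec.with_annotations([rec.annotation("3p")])
        c = dicer.derive_dicer_truth(pm, only3)
        assert c.position == rec.truth[1] - rec.truth[0]

    def test_mature_end_in_terminal_loop_flags_irregular(self):
        rec = make_perfect_hairpin(26, 8, seed=11, flank_len=2)
        hp = drosha.prepare(rec)
        dc = drosha.enumerate_drosha(hp)[0]
        pm = dicer.build_premirna(hp, dc.cut, refold=False)
        loop_i5 = pm.path.loop_junction[0]
        bad = rec.with_annotations(
            [MatureAnnotation(
                start=dc.cut, end=dc.cut + loop_i5 + 3, arm="5p"
            )]
        )
        dicer.derive_dicer_truth(pm, bad)
        assert any("mature_in_loop" in f for f in pm.flags)


class TestPredictAndAssemble:
    def test_recovery_beats_random_argmax(self, bench):
        from conftest import evaluate_stages

        rows = evaluate_stages(
            bench["test"], bench["test_folded"],
            bench["drosha_model"], bench["dicer_model"],
        )
        dicer_rows = [r[4] for r in rows if r[4] is not None]
        hits = sum(abs(pred - truth) <= 2 for _, pred, truth in dicer_rows)
        baseline = np.mean([1 / len(cands) for cands, _, _ in dicer_rows])
        assert hits / len(dicer_rows) >= 3 * baseline

    def test_mature_lengths_and_overhangs_on_perfect_hairpin(self, bench):
        rec = make_perfect_hairpin(30, 8, seed=12, flank_len=20)
        hp = drosha.prepare(rec)
        dc = drosha.enumerate_drosha(hp)[0]
        pm = dicer.build_premirna(hp, dc.cut, refold=True)
        cut, _, _ = dicer.predict_dicer(pm, bench["dicer_model"])
        mp = dicer.assemble_mature(hp, dc.cut, cut.position, pm)
        m5_len = mp.mature5p[1] - mp.mature5p[0]
        assert m5_len == cut.position and 16 <= m5_len <= 25
        assert mp.mature5p_seq == rec.sequence[mp.mature5p[0] : mp.mature5p[1]]
        # both duplex ends carry 2-nt 3' overhangs on a perfect stem
        pt = hp.pair_table
        assert mp.mature3p[1] - 1 == pt[mp.mature5p[0]] + 2
        assert mp.mature5p[1] - 1 == pt[mp.mature3p[0]] + 2

    def test_length_only_mask_trains_and_predicts(self, bench, cfg):
        from mircleave import pipeline

        model = pipeline.train_dicer_stage(
            bench["train_folded"][:80], cfg, feature_mask=LENGTH_ONLY_MASK
        )
        rec, hp = prepared(seed=14)
        pm = dicer.build_premirna(hp, rec.truth[0], refold=True)
        cut, score, cands = dicer.predict_dicer(pm, model)
        assert cut.position in {c.cut for c in cands}
        assert 0.0 <= score <= 1.0

    def test_length_only_mask_agrees_on_structureless_candidates(self, cfg):
        """When all candidates share identical structural features (perfect
        stems), a length-only forest and a full forest trained on the same
        perfect-stem data rank by length alone."""
        from mircleave import pipeline

        recs = []
        for i in range(40):
            rec = make_perfect_hairpin(28, 8, seed=100 + i, flank_len=12)
            # plant a fixed-length mature so length is informative
            d = drosha.enumerate_drosha(drosha.prepare(rec))[0].cut
            rec.annotations = [
                MatureAnnotation(start=d, end=d + 22, arm="5p")
            ]
            recs.append(rec)
        full = pipeline.train_dicer_stage(recs, cfg)
        masked = pipeline.train_dicer_stage(recs, cfg, feature_mask=LENGTH_ONLY_MASK)
        probe = make_perfect_hairpin(28, 8, seed=999, flank_len=12)
        hp = drosha.prepare(probe)
        d = drosha.enumerate_drosha(hp)[0].cut
        pm = dicer.build_premirna(hp, d, refold=True)
        cut_full, _, _ = dicer.predict_dicer(pm, full)
        cut_masked, _, _ = dicer.predict_dicer(pm, masked)
        assert cut_full.position == cut_masked.position == 22
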