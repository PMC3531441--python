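"""Stack-face energies: element values, splitting, windows and patterns.

The independent oracle for stack energies builds a reference duplex
hairpin, evaluates it with eval_structure twice (with and without one
pair), and subtracts — a different evaluator route from the per-loop calls
the implementation uses.
"""

import numpy as np
import pytest

from mircleave.energy import (
    EnergyModel,
    average_pattern,
    element_energy,
    face_profile,
    pattern_correlation,
    profile_window,
    stem_energy_oracle,
)
from mircleave.structure import decompose_stem, parse_dotbracket, select_stemloop
from mircleave.synthetic import GenParams, make_perfect_hairpin, plant_hairpin


class TestElementEnergy:
    def test_gc_stack_value(self):
        # stack of two GC pairs inside a reference duplex, by subtraction
        pairs = ["GC", "GC", "GC", "AU", "AU"]
        arm5 = "".join(p[0] for p in pairs)
        arm3 = "".join(p[1] for p in reversed(pairs))
        seq = arm5 + "AAAA" + arm3
        m = EnergyModel(seq)
        pt = parse_dotbracket(seq, "(((((....)))))")
        path = select_stemloop(pt)
        elems = decompose_stem(pt, path)
        stacks = [e for e in elems if e.kind == "stack"]
        gc_on_gc = element_energy(stacks[-1], seq, m)  # outermost step: GC/GC
        assert gc_on_gc == pytest.approx(-3.3, abs=0.2)
        # oracle route: full minus structure missing the innermost-but-one pair
        full_e = m.structure_energy("(((((....)))))")
        partial = m.structure_energy(".((((....)))).")
        missing_stack = full_e - partial
        assert missing_stack == pytest.approx(gc_on_gc, abs=1e-4)

    def test_au_stack_weaker_than_any_gc_stack(self):
        seqs = {
            "AU_on_AU": ["GC", "AU", "AU", "GC", "GC"],
            "GC_on_GC": ["GC", "GC", "GC", "GC", "GC"],
        }
        energies = {}
        for name, pairs in seqs.items():
            arm5 = "".join(p[0] for p in pairs)
            arm3 = "".join(p[1] for p in reversed(pairs))
            seq = arm5 + "AAAA" + arm3
            m = EnergyModel(seq)
            pt = parse_dotbracket(seq, "(((((....)))))")
            elems = decompose_stem(pt, select_stemloop(pt))
            # the step between helix pairs 2 and 3 (0-based from the base)
            energies[name] = element_energy(elems[-3], seq, m)
        assert energies["AU_on_AU"] < 0
        assert energies["GC_on_GC"] < energies["AU_on_AU"]

    def test_bulge_is_destabilizing(self):
        seq = "GGGG" + "A" + "GGGG" + "AAAA" + "CCCC" + "CCCC"
        db = "((((" + "." + "((((" + "...." + "))))" + "))))"
        pt = parse_dotbracket(seq, db)
        elems = decompose_stem(pt, select_stemloop(pt))
        bulge = next(e for e in elems if e.kind == "bulge")
        assert element_energy(bulge, seq) > 0


class TestFaceProfile:
    def test_perfect_stem_faces_are_stack_energies(self):
        rec = make_perfect_hairpin(10, 4, seed=0)
        pt = parse_dotbracket(rec.sequence, rec.structure)
        path = select_stemloop(pt)
        m = EnergyModel(rec.sequence)
        prof = face_profile(path, rec.sequence, m)
        elems = [e for e in decompose_stem(pt, path) if e.kind == "stack"]
        assert len(prof) == 9
        face_by_boundary = {f.boundary: f.energy for f in prof.faces}
        for e in elems:
            assert face_by_boundary[e.inner[0]] == pytest.approx(
                element_energy(e, rec.sequence, m)
            )

    def test_loop_faces_split_equally_and_conserve(self):
        seq = "GGGG" + "AA" + "GGG" + "AAAA" + "CCC" + "AAA" + "CCCC"
        db = "((((" + ".." + "(((" + "...." + ")))" + "..." + "))))"
        pt = parse_dotbracket(seq, db)
        path = select_stemloop(pt)
        m = EnergyModel(seq)
        il = next(e for e in decompose_stem(pt, path) if e.kind == "internal_loop")
        dg = element_energy(il, seq, m)
        prof = face_profile(path, seq, m)
        il_faces = [f for f in prof.faces if f.source == "internal_loop"]
        assert len(il_faces) == il.unpaired5 + 1 == 3
        assert all(f.energy == pytest.approx(dg / 3) for f in il_faces)
        assert sum(f.energy for f in il_faces) == pytest.approx(dg)

    def test_profile_length_formula(self):
        for seed in range(10):
            rec = plant_hairpin(GenParams(seed=9, signal_strength=0.5), seed=seed)
            pt = parse_dotbracket(rec.sequence, rec.structure)
            path = select_stemloop(pt, anchor=len(rec.sequence) // 2)
            prof = face_profile(path, rec.sequence)
            elems = decompose_stem(pt, path)
            expected = sum(
                1 if e.kind == "stack" else e.unpaired5 + 1
                for e in elems
                if e.kind != "terminal_loop"
            )
            assert len(prof) == expected

    def test_maxarm_split_adds_faces(self):
        seq = "GGGG" + "A" + "GGG" + "AAAA" + "CCC" + "AAA" + "CCCC"
        db = "((((" + "." + "(((" + "...." + ")))" + "..." + "))))"
        pt = parse_dotbracket(seq, db)
        path = select_stemloop(pt)
        arm5 = face_profile(path, seq, loop_split="arm5")
        maxarm = face_profile(path, seq, loop_split="maxarm")
        assert len(maxarm) > len(arm5)  # 1x3 loop: 2 faces vs 4

    def test_unstructured_input_has_no_faces(self):
        with pytest.raises(Exception):
            select_stemloop(parse_dotbracket("AAAAAA", "......"))


class TestWindow:
    def _profile(self):
        rec = make_perfect_hairpin(30, 6, seed=1)
        pt = parse_dotbracket(rec.sequence, rec.structure)
        path = select_stemloop(pt)
        return face_profile(path, rec.sequence), path

    def test_full_window_has_no_padding(self):
        prof, path = self._profile()
        vals, padded = profile_window(prof, origin=25, lo=0, hi=19)
        assert len(vals) == 20 and not padded.any()

    def test_window_beyond_base_pads_with_zero(self):
        prof, path = self._profile()
        base = path.base_junction[0]
        vals, padded = profile_window(prof, origin=base + 5, lo=0, hi=9)
        assert padded.sum() == 5
        assert (vals[padded] == 0.0).all()
        assert (vals[~padded] != 0.0).all()

    def test_single_face_window(self):
        prof, _ = self._profile()
        vals, padded = profile_window(prof, origin=10, lo=0, hi=0)
        assert len(vals) == 1 and not padded[0]
        assert vals[0] == prof.face_at(10).energy

    def test_invalid_window_rejected(self):
        prof, _ = self._profile()
        with pytest.raises(ValueError, match="lo"):
            profile_window(prof, origin=10, lo=5, hi=2)


class TestPattern:
    def test_identical_patterns_correlate_perfectly(self):
        v = np.arange(20.0)
        assert pattern_correlation(v, v) == pytest.approx(1.0)

    def test_sign_flip_anticorrelates(self):
        v = np.arange(20.0)
        assert pattern_correlation(v, -v) == pytest.approx(-1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pattern_correlation(np.ones(20), np.arange(20.0))

    def test_average_is_positionwise_midpoint(self):
        a = (np.full(5, -2.0), np.zeros(5, dtype=bool))
        b = (np.full(5, -4.0), np.zeros(5, dtype=bool))
        assert np.allclose(average_pattern([a, b]), -3.0)

    def test_padded_positions_excluded_from_mean(self):
        a = (np.array([-2.0, 0.0]), np.array([False, True]))
        b = (np.array([-4.0, -6.0]), np.array([False, False]))
        mean = average_pattern([a, b])
        assert mean[0] == pytest.approx(-3.0)
        assert mean[1] == pytest.approx(-6.0)  # only the unpadded value

    def test_species_style_pattern_self_consistency(self):
        """Mean planted-signal pattern correlates with itself across two
        disjoint cohorts (the cross-cohort analogue of the conserved
        vertebrate pattern), while random-composition cohorts need not."""
        from mircleave import drosha

        def cohort_pattern(seed, signal):
            windows = []
            for i in range(40):
                rec = plant_hairpin(
                    GenParams(seed=seed, signal_strength=signal), seed=i
                )
                hp = drosha.prepare(rec)
                d = drosha.derive_drosha_truth(hp).position
                windows.append(profile_window(hp.profile, d, 0, 19))
            return average_pattern(windows)

        p1 = cohort_pattern(21, 1.0)
        p2 = cohort_pattern(22, 1.0)
        assert pattern_correlation(p1, p2) > 0.8


class TestConservation:
    @pytest.mark.parametrize("seed", range(25))
    def test_element_sum_matches_eval_structure_difference(self, seed):
        rec = plant_hairpin(GenParams(seed=12, signal_strength=0.5), seed=seed)
        pt = parse_dotbracket(rec.sequence, rec.structure)
        path = select_stemloop(pt, anchor=len(rec.sequence) // 2)
        m = EnergyModel(rec.sequence)
        total = sum(
            element_energy(e, rec.sequence, m)
            for e in decompose_stem(pt, path)
            if e.kind != "terminal_loop"
        )
        oracle = stem_energy_oracle(rec.sequence, pt, path)
        assert total == pytest.approx(oracle, abs=0.5 + 1e-3)
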