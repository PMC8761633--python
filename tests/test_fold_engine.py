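"""Folding engine: energy model integrity, MFE optimality against
exhaustive enumeration, structure evaluation, and region attribution."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_mfe, enumerate_structures, random_rna
from mirproc.fold_engine import (EnergyModel, evaluate_structure_energy,
                                 fold_mfe, loop_decomposition,
                                 pair_table_from_dotbracket, read_folds,
                                 region_energy, write_fold)


class TestEnergyModel:
    def test_stack_table_is_flip_symmetric(self, model):
        flip = {"AU": "UA", "UA": "AU", "GC": "CG", "CG": "GC",
                "GU": "UG", "UG": "GU"}
        for (p1, p2), e in model.stack_energies.items():
            assert e == model.stack_energies[(flip[p2], flip[p1])]

    def test_loop_penalties_defined_and_extrapolate(self, model):
        assert model.hairpin_ci(3) > 0
        # logarithmic growth beyond the tabulated sizes
        assert model.hairpin_ci(80) > model.hairpin_ci(30) > 0
        assert model.bulge_ci(50) > model.bulge_ci(30)
        with pytest.raises(ValueError):
            model.hairpin_ci(2)


class TestFoldMfe:
    def test_unpairable_sequence_is_open_chain(self):
        fr = fold_mfe("AAAAAA")
        assert fr.dotbracket == "......"
        assert fr.delta_g == 0.0

    def test_simple_hairpin_hand_computed(self, model):
        # three G-C pairs, two GC-on-GC stacks (-3.26 each) plus a 4-nt
        # hairpin loop (+5.60) -> -0.92 kcal/mol for the fully paired structure
        e = evaluate_structure_energy("GGGAAAACCC", "(((....)))", model)
        assert e == pytest.approx(model.stack_energies[("GC", "GC")] * 2 + 5.60,
                                  abs=1e-9)
        assert e == pytest.approx(-0.92, abs=1e-9)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGN")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed, model):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(5):
            seq = random_rna(rng, int(rng.integers(8, 19)))
            fr = fold_mfe(seq, model)
            e_ci, db = brute_force_mfe(seq, model)
            assert fr._dg_ci == e_ci
            assert fr.dotbracket == db

    def test_mfe_not_above_any_enumerated_structure(self, model):
        rng = np.random.default_rng(7)
        seq = random_rna(rng, 14)
        fr = fold_mfe(seq, model)
        for db in enumerate_structures(seq):
            assert fr._dg_ci <= round(
                100 * evaluate_structure_energy(seq, db, model)) + 1e-9

    def test_nonpairing_spacer_keeps_deltaG_nonpositive(self, model):
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = random_rna(rng, 12) + "AAAAAA"
            assert fold_mfe(seq, model).delta_g <= 0.0

    def test_deterministic_across_runs(self):
        seq = "GGCGAAAGCGCCAUAGGCGC"
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert a.dotbracket == b.dotbracket
        assert a.delta_g == b.delta_g

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=16))
    def test_self_consistency_evaluate_equals_fold(self, seq):
        fr = fold_mfe(seq)
        assert evaluate_structure_energy(seq, fr.dotbracket) == fr.delta_g


class TestStructureEvaluation:
    def test_open_chain_is_zero(self):
        assert evaluate_structure_energy("ACGUACGU", "........") == 0.0

    @pytest.mark.parametrize("seq,db", [
        ("CAAAAAAC", "((....))"),   # disallowed A-A inner pair
        ("GAA", "(()"),             # unbalanced brackets
        ("GAAC", "(..)"),           # hairpin loop below 3 unpaired
        ("GGGAAAACCC", "(((....))"),  # length mismatch
    ])
    def test_invalid_structures_rejected(self, seq, db):
        with pytest.raises(ValueError):
            evaluate_structure_energy(seq, db)

    def test_pair_table_involution(self):
        pt = pair_table_from_dotbracket("((..))..(...)")
        for i, q in enumerate(pt):
            if q:
                assert pt[q - 1] == i + 1


class TestRegionEnergy:
    def test_full_region_equals_total(self, model):
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = random_rna(rng, 30)
            fr = fold_mfe(seq, model)
            full = region_energy(seq, fr.dotbracket, [(1, len(seq))], model)
            assert full == fr.delta_g

    def test_unpaired_loop_region_excludes_closing_pair(self, model):
        # hairpin-loop term participants include the closing pair, so a
        # region holding only the unpaired loop positions gets none of it
        seq, db = "GGGAAAACCC", "(((....)))"
        assert region_energy(seq, db, [(4, 7)], model) == 0.0
        # widening the region to the closing pair captures the loop penalty
        assert region_energy(seq, db, [(3, 8)], model) == pytest.approx(5.60)

    def test_two_span_region_captures_outer_stacks(self, model):
        # outermost three pairs of a toy hairpin: exactly two stack terms
        seq, db = "GGGGAAAACCCC", "((((....))))"
        terms = loop_decomposition(seq, db, model)
        stacks = [t for t in terms if t.kind == "stack"]
        expected = sum(t.energy_ci for t in stacks
                       if t.participants <= set(range(0, 3)) | set(range(9, 12)))
        got = region_energy(seq, db, [(1, 3), (10, 12)], model)
        assert got == pytest.approx(expected / 100.0)

    def test_partition_along_decomposition_boundaries_is_additive(self, model):
        # regions sharing only the boundary pair (3,10) split the terms
        # cleanly: outer two stacks vs inner stack + hairpin loop
        seq, db = "GGGGAAAACCCCAAA", "((((....))))..."
        apical = region_energy(seq, db, [(3, 10)], model)
        basal = region_energy(seq, db, [(1, 3), (10, 15)], model)
        total = evaluate_structure_energy(seq, db, model)
        assert apical + basal == pytest.approx(total)

    def test_out_of_bounds_region_rejected(self, model):
        with pytest.raises(ValueError):
            region_energy("GGGAAAACCC", "(((....)))", [(5, 11)], model)


def test_deltaG_ordering_tracks_reference_folder(small_cohort):
    """Independent cross-check: on hairpin-shaped sequences the engine's ΔG
    ordering agrees with a reference thermodynamic folder (RNAfold), even
    though the parameter sets differ in detail."""
    import subprocess
    from scipy.stats import spearmanr
    seqs = [r.sequence for r in small_cohort.records[:25]]
    res = subprocess.run(["RNAfold", "--noPS"], input="\n".join(seqs),
                         capture_output=True, text=True, check=True)
    lines = res.stdout.strip().splitlines()
    ours, ref = [], []
    for i, seq in enumerate(seqs):
        db_line = lines[2 * i + 1]
        ref.append(float(db_line[db_line.rfind("(") + 1:db_line.rfind(")")]))
        ours.append(fold_mfe(seq).delta_g)
    assert spearmanr(ours, ref).statistic > 0.8


def test_dotbracket_record_roundtrip(tmp_path):
    fr = fold_mfe("GGGAAAACCC")
    path = tmp_path / "folds.db"
    write_fold(path, "toy", fr)
    back = read_folds(path)["toy"]
    assert back.dotbracket == fr.dotbracket
    assert back.delta_g == fr.delta_g
    assert back.sequence == fr.sequence
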