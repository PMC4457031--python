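"""Variant-site QC, the exclusion cascade, digest and truncation."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recmap
from recmap import Interval
from recmap.io import GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING
from recmap.variant_screen import (
    cosegregation_check,
    insilico_rflp,
    mendelian_recessive_filter,
    population_screen,
    predict_truncation,
    variant_site_qc,
)

from conftest import make_digest_fixture, make_pedigree


def _variants(rows):
    defaults = {
        "chrom": "18",
        "ref": "A",
        "alt": "T",
        "qual": 60.0,
        "depth": 40.0,
        "gene": "g1",
        "func_class": "coding_nonsyn",
        "gt_affected": GT_HOMALT,
        "gt_sire": GT_HET,
        "gt_dam": GT_HET,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.update(row)
        r.setdefault("id", f"v{i + 1}")
        out.append(r)
    return pd.DataFrame(out)


class TestSiteQc:
    @pytest.mark.parametrize(
        "depth,kept", [(5, False), (6, True), (70, True), (71, False)]
    )
    def test_depth_bounds_inclusive(self, depth, kept):
        v = _variants([{"pos": 100, "depth": float(depth)}])
        out, trace = variant_site_qc(v)
        assert (len(out) == 1) is kept

    def test_spacing_rule_uses_previous_seen_variant(self):
        v = _variants([{"pos": 100}, {"pos": 103}, {"pos": 200}])
        out, trace = variant_site_qc(v)
        assert out["pos"].tolist() == [100, 200]
        assert trace.to_frame().set_index("step").loc["spacing", "n_removed"] == 1

    def test_quality_threshold(self):
        v = _variants([{"pos": 100, "qual": 19.9}, {"pos": 200, "qual": 20.0}])
        out, _ = variant_site_qc(v)
        assert out["pos"].tolist() == [200]

    def test_empty_input(self):
        out, trace = variant_site_qc(_variants([]).reindex(columns=["chrom", "pos", "depth", "qual", "id"]))
        assert out.empty and trace.steps == []

    def test_unsorted_input_rejected(self):
        v = _variants([{"pos": 200}, {"pos": 100}])
        with pytest.raises(ValueError, match="sorted"):
            variant_site_qc(v)

    def test_trace_conserves_counts(self):
        v = _variants(
            [{"pos": p, "depth": d} for p, d in [(10, 3), (100, 40), (103, 40), (300, 90)]]
        )
        _, trace = variant_site_qc(v)
        for step in trace.steps:
            assert step.n_in - step.n_removed == len(step.surviving_ids)


class TestMendelianCascade:
    def test_five_variant_toy_one_removal_per_step(self):
        v = _variants(
            [
                {"pos": 100, "gt_affected": GT_HET},  # step 1
                {"pos": 200, "gt_sire": GT_HOMALT},  # step 2
                {"pos": 300, "gt_sire": GT_HOMREF, "gt_dam": GT_HOMREF},  # step 3
                {"pos": 400, "func_class": "noncoding"},  # step 4
                {"pos": 500, "func_class": "coding_truncating"},  # survivor
            ]
        )
        out, trace = mendelian_recessive_filter(v, "affected", "sire", "dam")
        assert out["pos"].tolist() == [500]
        assert [s.n_removed for s in trace.steps] == [1, 1, 1, 1]
        assert [s.name for s in trace.steps] == [
            "not_homalt_in_affected",
            "parent_homalt",
            "mendelian_inconsistent",
            "noncoding",
        ]

    def test_missing_genotype_removed_at_evaluating_step(self):
        v = _variants([{"pos": 100, "gt_affected": GT_MISSING}, {"pos": 200, "gt_dam": GT_MISSING}])
        out, trace = mendelian_recessive_filter(v, "affected", "sire", "dam")
        assert out.empty
        assert trace.steps[0].n_removed == 1  # missing affected call
        assert trace.steps[1].n_removed == 1  # missing parent call

    def test_empty_input_zero_trace(self):
        v = _variants([{"pos": 1}]).iloc[0:0]
        out, trace = mendelian_recessive_filter(v, "affected", "sire", "dam")
        assert out.empty and all(s.n_removed == 0 for s in trace.steps)

    def test_absent_sample_column_errors(self):
        v = _variants([{"pos": 100}])
        with pytest.raises(ValueError, match="absent"):
            mendelian_recessive_filter(v, "affected", "sire", "nobody")

    def test_planted_variant_survives_simulated_trios(self):
        iv = Interval(chrom="18", start_bp=48_877_373, end_bp=50_901_463)
        for seed in range(1, 4):
            var, truth = recmap.simulate_trio_variants(seed=seed, interval=iv)
            out, _ = mendelian_recessive_filter(var, "affected", "sire", "dam")
            assert truth.causal_variant_id in set(out["id"])


class TestPopulationScreen:
    def _with_panel(self, freqs, panel_size=10):
        rows = []
        for i, f in enumerate(freqs):
            row = {"pos": 100 * (i + 1)}
            n_alt = round(f * 2 * panel_size)
            gts = []
            while n_alt >= 2:
                gts.append(GT_HOMALT)
                n_alt -= 2
            if n_alt == 1:
                gts.append(GT_HET)
            gts += [GT_HOMREF] * (panel_size - len(gts))
            for k, g in enumerate(gts):
                row[f"gt_P{k + 1}"] = g
            rows.append(row)
        return _variants(rows), [f"P{k + 1}" for k in range(panel_size)]

    def test_segregating_above_threshold_removed(self):
        v, panel = self._with_panel([0.15])
        out, trace = population_screen(v, panel)
        assert out.empty and trace.steps[0].n_removed == 1

    def test_absent_retained(self):
        v, panel = self._with_panel([0.0])
        out, _ = population_screen(v, panel)
        assert len(out) == 1 and out["panel_flag"].iloc[0] == "absent"

    def test_low_frequency_retained_ambiguous(self):
        v, panel = self._with_panel([0.05])
        out, _ = population_screen(v, panel)
        assert len(out) == 1 and out["panel_flag"].iloc[0] == "ambiguous"

    def test_empty_panel_errors(self):
        v, _ = self._with_panel([0.0])
        with pytest.raises(ValueError, match="panel"):
            population_screen(v, [])


class TestCosegregation:
    def test_perfect_recessive_pattern_passes(self):
        ped = make_pedigree(n_f2=4, affected=("F2_1",))
        gts = {
            "F0_A": GT_HOMREF,
            "F0_B": GT_HET,
            "F1_1": GT_HET,
            "F1_2": GT_HET,
            "F2_1": GT_HOMALT,
            "F2_2": GT_HET,
            "F2_3": GT_HOMREF,
            "F2_4": GT_HET,
        }
        passes, counts = cosegregation_check(ped, gts)
        assert passes
        assert counts.loc[GT_HOMALT, "affected"] == 1

    def test_unaffected_homalt_fails(self):
        ped = make_pedigree(n_f2=2, affected=("F2_1",))
        gts = {i: GT_HET for i in ped.iids}
        gts["F2_1"] = GT_HOMALT
        gts["F2_2"] = GT_HOMALT
        passes, _ = cosegregation_check(ped, gts)
        assert not passes

    def test_missing_affected_genotype_errors(self):
        ped = make_pedigree(n_f2=1, affected=("F2_1",))
        with pytest.raises(ValueError, match="missing genotype"):
            cosegregation_check(ped, {i: GT_HET for i in ped.iids if i != "F2_1"})

    def test_simulated_planted_variant_cosegregates(self):
        ped, _, truth = recmap.simulate_f2_cross(seed=21, n_f2=40, n_markers=60)
        code = {0: GT_HOMREF, 1: GT_HET, 2: GT_HOMALT}
        gts = {i: code[c] for i, c in truth.carrier_copies.items()}
        passes, _ = cosegregation_check(ped, gts)
        assert passes


class TestRflp:
    def test_no_site_returns_whole_length(self):
        assert insilico_rflp("ATATATAT") == [8]

    def test_hand_cut_arithmetic(self):
        assert insilico_rflp("ACCCGGGT") == [4, 4]

    def test_printed_fragment_sizes(self):
        seq = make_digest_fixture(total=891, cut_at=438)
        assert insilico_rflp(seq) == [438, 453]

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="A,C,G,T"):
            insilico_rflp("ACGTN")

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_fragments_conserve_length_and_count(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 400)))
        site = "CCCGGG"
        frags = insilico_rflp(seq, site, 3)
        assert sum(frags) == len(seq)
        interior = [
            m.start() + 3 for m in re.finditer(f"(?={site})", seq) if 0 < m.start() + 3 < len(seq)
        ]
        assert len(frags) == len(set(interior)) + 1

    def test_non_palindromic_site_cut_on_both_strands(self):
        # GACGTC is palindromic; use GGTCTC (BsaI-like) to exercise reverse hits
        seq = "AAAGGTCTCAAAAAGAGACCAAA"
        frags = insilico_rflp(seq, "GGTCTC", 1)
        assert sum(frags) == len(seq)
        assert len(frags) == 3


class TestTruncation:
    CDS = "ATG" + "GCT" * 60 + "TAA"  # Met + 60 Ala + stop

    def _oracle_first_stop(self, seq):
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        table = unambiguous_dna_by_id[1]
        for k in range(len(seq) // 3):
            codon = seq[3 * k : 3 * k + 3]
            if codon in table.stop_codons:
                return k + 1
        return None

    def test_synonymous_substitution_no_premature_stop(self):
        # GCT -> GCC (both Ala) at codon 2
        length, stop = predict_truncation(self.CDS, (6, "T", "C"))
        assert stop is None and length == 61

    def test_frameshift_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * 40))
            pos = int(rng.integers(4, len(cds) - 4))
            deleted = cds[pos - 1]
            inserted = "TC"  # 1-bp deletion + 2-bp insertion: net frameshift
            edited = cds[: pos - 1] + inserted + cds[pos:]
            got_len, got_stop = predict_truncation(cds, (pos, deleted, inserted))
            orig_stop = self._oracle_first_stop(cds)
            orig_len = (orig_stop - 1) if orig_stop else len(cds) // 3
            new_stop = self._oracle_first_stop(edited)
            new_len = (new_stop - 1) if new_stop else len(edited) // 3
            exp_stop = new_stop if (new_stop is not None and new_len < orig_len) else None
            assert got_stop == exp_stop
            assert got_len == new_len

    def test_immediate_inframe_stop(self):
        # replace codon 5 (GCT) with TAA
        length, stop = predict_truncation(self.CDS, (13, "GCT", "TAA"))
        assert stop == 5 and length == 4

    def test_position_beyond_cds_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            predict_truncation(self.CDS, (10_000, "A", "T"))
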