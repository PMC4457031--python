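"""RPKM, the Poisson exact test, FDR, DEG calling and allied operations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recmap
from recmap.expression import (
    CALL_DOWN,
    CALL_NS,
    CALL_UP,
    CountTable,
    ac_equal_expression_test,
    ac_pointwise_log_p,
    bh_fdr,
    call_degs,
    ddct_fold_change,
    merge_deg_lists,
    overrepresentation_test,
    rpkm,
)


class TestRpkm:
    def test_zero_count_gives_zero(self):
        assert rpkm(0, 10**6, 1000) == 0.0

    def test_stated_formula_arithmetic(self):
        assert rpkm(10, 2_000_000, 500) == pytest.approx(10.0)

    def test_linearity(self):
        base = rpkm(7, 1_000_000, 800)
        assert rpkm(14, 1_000_000, 800) == pytest.approx(2 * base)
        assert rpkm(7, 2_000_000, 800) == pytest.approx(base / 2)

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


def brute_force_two_sided(x, y, n1, n2):
    """Tail sums over the conditional law, summed term by term."""
    r = n2 / n1

    def log_pw(k):
        return (
            k * math.log(r)
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * math.log1p(r)
        )

    lower = sum(math.exp(log_pw(k)) for k in range(y + 1))
    upper = 1.0 - sum(math.exp(log_pw(k)) for k in range(y))
    return min(1.0, 2.0 * min(lower, upper))


class TestAcTest:
    @pytest.mark.parametrize("x,y,expected", [(0, 0, 0.5), (1, 1, 0.25)])
    def test_equal_library_closed_form(self, x, y, expected):
        pw, _ = ac_equal_expression_test(x, y, 1000, 1000)
        assert pw == pytest.approx(expected, abs=1e-12)

    def test_equal_library_pointwise_is_binomial_form(self):
        # with N1 = N2 the pointwise law reduces to C(x+y, x) / 2^(x+y+1)
        for x, y in [(3, 5), (10, 2), (0, 7), (20, 20)]:
            pw, _ = ac_equal_expression_test(x, y, 5_000, 5_000)
            exact = math.comb(x + y, x) / 2 ** (x + y + 1)
            assert pw == pytest.approx(exact, rel=1e-12)

    def test_tails_match_brute_force_sample(self):
        for x, y, r in [(0, 10, 1.0), (25, 5, 0.5), (40, 50, 2.0), (7, 7, 1.0)]:
            n1 = 1_000_000
            _, p2 = ac_equal_expression_test(x, y, n1, int(n1 * r))
            assert p2 == pytest.approx(brute_force_two_sided(x, y, n1, int(n1 * r)), abs=1e-10)

    def test_symmetry_under_sample_swap(self):
        # the doubled inclusive-tail convention is symmetric only up to the
        # observed points' probability mass: the tail identity
        # P(Y>y|x; N1,N2) = P(X<=x|y; N2,N1) bounds the gap
        for x, y, n1, n2 in [
            (3, 11, 10**6, 10**6),
            (17, 2, 10**6, 2 * 10**6),
            (9, 9, 10**6, 2 * 10**6),
            (0, 4, 10**6, 10**6),
        ]:
            pw_xy, a = ac_equal_expression_test(x, y, n1, n2)
            pw_yx, b = ac_equal_expression_test(y, x, n2, n1)
            assert abs(a - b) <= 2 * (pw_xy + pw_yx) + 1e-12

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=25, deadline=None)
    def test_pointwise_law_normalizes(self, x):
        ys = np.arange(0, 4000)
        total = np.exp(ac_pointwise_log_p(np.full_like(ys, x), ys, 3_000_000, 1_500_000)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_minlike_variant_bounded_by_one_and_close_to_doubled(self):
        _, doubled = ac_equal_expression_test(10, 30, 10**6, 10**6)
        _, minlike = ac_equal_expression_test(10, 30, 10**6, 10**6, two_sided="minlike")
        assert 0 <= minlike <= 1
        assert minlike <= 2 * doubled


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_manual_oracle_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            p = rng.random(n)
            q = bh_fdr(p)
            order = np.argsort(p)
            stepped = p[order] * n / np.arange(1, n + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(n)
            expected[order] = np.minimum(stepped, 1.0)
            assert np.allclose(q, expected)

    def test_invariant_to_input_order(self):
        p = np.array([0.5, 0.001, 0.2, 0.04])
        perm = [2, 0, 3, 1]
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


def _count_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "length_bp", "x", "y"])
    return CountTable(table=df)


class TestCallDegs:
    def test_double_zero_genes_excluded(self):
        ct = _count_table([("g1", 500, 0, 0), ("g2", 500, 50, 60), ("g3", 400, 10, 0)])
        deg = call_degs(ct)
        assert set(deg["gene_id"]) == {"g2", "g3"}

    def test_single_zero_passes_fold_criterion(self):
        ct = _count_table([("g1", 500, 400, 0)] + [(f"b{i}", 500, 50, 50) for i in range(20)])
        deg = call_degs(ct).set_index("gene_id")
        assert np.isinf(deg.loc["g1", "log2_ratio"])
        assert deg.loc["g1", "call"] == CALL_DOWN

    def test_direction_labels_relative_to_mutant(self):
        rows = [("up", 500, 20, 800), ("down", 500, 800, 20)] + [
            (f"b{i}", 500, 100, 100) for i in range(30)
        ]
        deg = call_degs(_count_table(rows)).set_index("gene_id")
        assert deg.loc["up", "call"] == CALL_UP
        assert deg.loc["down", "call"] == CALL_DOWN

    def test_sample_swap_flips_log2_sign(self):
        rows = [("g1", 500, 30, 90), ("g2", 300, 200, 100)]
        a = call_degs(_count_table(rows)).set_index("gene_id")
        swapped = [(g, L, y, x) for g, L, x, y in rows]
        b = call_degs(_count_table(swapped)).set_index("gene_id")
        assert a["log2_ratio"]["g1"] == pytest.approx(-b["log2_ratio"]["g1"])

    def test_gene_order_invariance(self):
        rows = [(f"g{i}", 200 + i, 10 * i, 12 * i) for i in range(1, 8)]
        a = call_degs(_count_table(rows)).set_index("gene_id").sort_index()
        b = call_degs(_count_table(rows[::-1])).set_index("gene_id").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_null_simulation_calls_almost_nothing(self):
        fracs = []
        for seed in range(1, 6):
            ct, _ = recmap.simulate_counts(seed=seed, n_genes=1000, n_de=0)
            deg = call_degs(ct)
            fracs.append((deg["call"] != CALL_NS).mean())
        assert np.mean(fracs) <= 0.01

    def test_planted_fold_changes_recovered_with_direction(self):
        ct, truth = recmap.simulate_counts(seed=3, n_genes=1500, n_de=80, log2fc=2.0)
        deg = call_degs(ct).set_index("gene_id")
        hits = dir_ok = 0
        for gene, lfc in truth.de_log2fc.items():
            if gene in deg.index and deg.loc[gene, "call"] != CALL_NS:
                hits += 1
                want = CALL_UP if lfc > 0 else CALL_DOWN
                dir_ok += deg.loc[gene, "call"] == want
        assert hits / len(truth.de_log2fc) >= 0.9
        assert dir_ok == hits

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            call_degs(CountTable(table=pd.DataFrame(columns=["gene_id", "length_bp", "x", "y"])))


class TestMergeAndQpcr:
    def test_printed_union_arithmetic(self):
        a = [f"a{i}" for i in range(167)] + [f"s{i}" for i in range(7)]  # 174
        b = [f"b{i}" for i in range(163)] + [f"s{i}" for i in range(7)]  # 170
        merged = merge_deg_lists(a, b)
        assert len(merged) == 337
        assert (merged["provenance"] == "both").sum() == 7

    def test_disjoint_and_identical(self):
        assert len(merge_deg_lists(["x", "y"], ["z"])) == 3
        assert len(merge_deg_lists(["x", "y"], ["X", "Y"])) == 2  # case-folded

    @pytest.mark.parametrize("ddct,fold", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_ddct_closed_form(self, ddct, fold):
        rows = []
        for group, dct in [("wildtype", 5.0), ("mutant", 5.0 + ddct)]:
            for _ in range(3):
                rows.append({"gene": "g", "group": group, "ct_target": 20.0 + dct, "ct_ref": 15.0})
        out = ddct_fold_change(pd.DataFrame(rows))
        assert out["g"] == pytest.approx(fold)

    def test_missing_group_errors(self):
        df = pd.DataFrame([{"gene": "g", "group": "wildtype", "ct_target": 20.0, "ct_ref": 15.0}])
        with pytest.raises(ValueError, match="lacks"):
            ddct_fold_change(df)


def hypergeom_upper_tail(k, m_universe, k_set, n_query):
    total = math.comb(m_universe, n_query)
    return sum(
        math.comb(k_set, i) * math.comb(m_universe - k_set, n_query - i) / total
        for i in range(k, min(k_set, n_query) + 1)
    )


class TestOverrepresentation:
    def test_gene_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = overrepresentation_test({"g1", "g2"}, {"all": universe}, universe)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(6)} | {f"g{i}" for i in range(50, 64)}  # overlap 6
        out = overrepresentation_test(query, {"s": gene_set}, universe)
        assert out["overlap"].iloc[0] == 6
        assert out["ratio"].iloc[0] == "6/10"
        assert out["p"].iloc[0] == pytest.approx(hypergeom_upper_tail(6, 100, 10, 20), rel=1e-9)

    def test_zero_overlap(self):
        universe = {f"g{i}" for i in range(40)}
        out = overrepresentation_test(
            {f"g{i}" for i in range(10)}, {"s": {f"g{i}" for i in range(30, 40)}}, universe
        )
        assert out["ratio"].iloc[0] == "0/10"
        assert out["p"].iloc[0] > 0.9

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            overrepresentation_test(set(), {"s": set()}, set())
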