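"""Fold enrichment, Fisher exact tests, BY correction, cell-type ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from listenrich import (
    by_adjust,
    celltype_enrich,
    fisher_exact_2x2,
    finalize_against,
    generate_celltype_db,
    marker_list_from_counts,
    overlap_enrichment,
    universe_from_counts,
)


def hypergeom_tail_oracle(a, b, c, d):
    """Exhaustive enumeration of the upper tail with exact integer binomials."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    return sum(math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, hi + 1)) / denom


class TestFisher:
    def test_empty_first_margin_gives_p_one(self):
        p, _ = fisher_exact_2x2(0, 0, 5, 7)
        assert p == 1.0

    def test_small_table_matches_enumeration(self):
        p, odds = fisher_exact_2x2(3, 1, 1, 3, "greater")
        assert p == pytest.approx(hypergeom_tail_oracle(3, 1, 1, 3), abs=1e-14)
        assert odds == 9.0

    def test_meta_list_table_below_printed_bound(self):
        p, _ = fisher_exact_2x2(28, 27, 351, 10497, "greater")
        assert p < 0.005

    @pytest.mark.parametrize("table", [(3, 1, 1, 3), (5, 10, 2, 40), (0, 4, 6, 2), (12, 0, 3, 9)])
    @pytest.mark.parametrize("sidedness,alternative", [("greater", "greater"), ("two_sided", "two-sided")])
    def test_matches_reference_library(self, table, sidedness, alternative):
        a, b, c, d = table
        p, odds = fisher_exact_2x2(a, b, c, d, sidedness)
        ref_odds, ref_p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        assert p == pytest.approx(ref_p, rel=1e-9)
        if not math.isnan(odds):
            assert odds == pytest.approx(ref_odds)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_monotone_in_overlap_with_fixed_margins(self):
        # moving one unit from b,c into a,d keeps margins, must not raise p
        prev = 1.0
        for a in range(0, 11):
            p, _ = fisher_exact_2x2(a, 10 - a, 10 - a, 20 + a, "greater")
            assert p <= prev + 1e-12
            prev = p

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_matches_enumeration_on_random_tables(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        lo, hi = max(0, n - (N - K)), min(K, n)
        a = data.draw(st.integers(lo, hi))
        b, c, d = K - a, n - a, N - K - n + a
        p, _ = fisher_exact_2x2(a, b, c, d, "greater")
        assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), abs=1e-12)


class TestOverlapEnrichment:
    def test_worked_example_meta_list(self):
        universe = universe_from_counts(10903, 379, 175)
        lst = marker_list_from_counts(universe, 55, 28, "meta")
        r = overlap_enrichment(lst, universe)
        assert r.overlap_fraction == pytest.approx(28 / 55)
        assert r.fold_enrichment > 14
        assert r.fisher_p < 0.005

    def test_chance_level_overlap_is_not_significant(self):
        universe = universe_from_counts(10903, 379, 175)
        lst = marker_list_from_counts(universe, 55, 2, "null")
        r = overlap_enrichment(lst, universe)
        assert r.overlap_fraction == pytest.approx(2 / 55)
        assert r.fold_enrichment == pytest.approx(1.0, rel=0.1)
        assert r.fisher_p > 0.05

    def test_entire_universe_as_list_has_fold_exactly_one(self):
        universe = universe_from_counts(200, 17)
        lst = finalize_against(universe.gene_ids(), universe, "all")
        r = overlap_enrichment(lst, universe)
        assert r.fold_enrichment == pytest.approx(1.0)
        assert r.n_overlap == 17

    def test_background_override_controls_fold(self):
        universe = universe_from_counts(10903, 379)
        lst = marker_list_from_counts(universe, 55, 28, "meta")
        r = overlap_enrichment(lst, universe, background=0.0348)
        assert r.fold_enrichment == pytest.approx((28 / 55) / 0.0348)

    def test_empty_detected_list_returns_degenerate_result(self):
        universe = universe_from_counts(100, 10)
        lst = finalize_against({"gX"}, universe, "ghost")
        r = overlap_enrichment(lst, universe)
        assert (r.fold_enrichment, r.fisher_p) == (0.0, 1.0)

    def test_modality_mismatch_rejected(self):
        t_universe = universe_from_counts(100, 10)
        p_universe = universe_from_counts(50, 5, modality="protein")
        lst = finalize_against(sorted(t_universe.gene_ids())[:5], t_universe, "demo")
        with pytest.raises(ValueError, match="modality|finalized"):
            overlap_enrichment(lst, p_universe)


class TestBYAdjust:
    def test_single_p_unchanged(self):
        assert by_adjust([0.03]) == pytest.approx([0.03])

    def test_five_values_match_by_hand_step_up(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.27]
        # textbook BY: c(5) = 1 + 1/2 + ... + 1/5, step-up with min-accumulate
        c5 = sum(1 / i for i in range(1, 6))
        raw = [c5 * 5 * pi / (i + 1) for i, pi in enumerate(p)]
        expected = [min(min(raw[i:]), 1.0) for i in range(5)]
        assert by_adjust(p) == pytest.approx(expected)

    def test_all_ones_stay_ones(self):
        assert by_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_dominates_bh(self, p):
        from statsmodels.stats.multitest import multipletests

        adj = by_adjust(sorted(p))
        assert (np.diff(adj) >= -1e-12).all()
        bh = multipletests(p, method="fdr_bh")[1]
        assert (by_adjust(p) >= bh - 1e-12).all()


class TestCellTypeEnrich:
    def test_perfect_match_term_ranks_first(self):
        universe = [f"g{i}" for i in range(500)]
        db = {"match": frozenset(universe[:20]), "other": frozenset(universe[100:140])}
        out = celltype_enrich(universe[:20], db, universe, alpha=0.05, top_n=5)
        assert out[0].term == "match" and out[0].rank == 1
        assert out[0].p_adjusted >= out[0].p_raw

    def test_tie_broken_by_adjusted_p_then_term_order(self):
        universe = [f"g{i}" for i in range(400)]
        query = universe[:30]
        db = {
            "b_tied": frozenset(universe[:10]),
            "a_tied": frozenset(universe[10:20]),
            "weak": frozenset(universe[300:350]),
        }
        out = celltype_enrich(query, db, universe, alpha=0.05, top_n=5)
        tied = [r for r in out if r.term.endswith("_tied")]
        assert [r.term for r in tied] == ["a_tied", "b_tied"]
        assert [r.rank for r in out] == list(range(1, len(out) + 1))

    def test_planted_term_recovered_across_replicates(self, universe1):
        genes = sorted(universe1.gene_ids())[:2000]
        query = genes[:60]
        hits = 0
        for rep in range(200):
            db = generate_celltype_db(genes, query, n_terms=10, markers_per_term=40,
                                      planted_query_frac=0.5, seed=rep)
            out = celltype_enrich(query, db, genes, alpha=0.05, top_n=20)
            if out and out[0].term == "activated_macrophage":
                hits += 1
        assert hits >= 190  # >= 95% of 200 seeded replicates

    def test_query_genes_outside_universe_are_filtered(self):
        universe = [f"g{i}" for i in range(200)]
        db = {"t": frozenset(universe[:10])}
        out = celltype_enrich(universe[:10] + ["alien"], db, universe, alpha=0.5, top_n=5)
        assert out[0].n_overlap == 10

    def test_empty_database_is_error(self):
        with pytest.raises(ValueError):
            celltype_enrich(["g1"], {}, ["g1"])
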