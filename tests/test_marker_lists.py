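"""Marker-list compilation: selection rules, combination, detection filtering,
and gene-to-protein mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from listenrich import (
    IdMap,
    MarkerStudy,
    SelectionRule,
    apply_selection_rule,
    combine,
    compile_from_config,
    finalize_against,
    generate_idmap,
    map_to_protein_universe,
    universe_from_counts,
)

genesets = st.sets(st.sampled_from([f"g{i}" for i in range(12)]), max_size=8)


def study(rows, rule, **cols):
    table = pd.DataFrame({"gene_id": rows, **cols})
    return MarkerStudy(study_id="s", table=table, rule=rule)


class TestSelectionRule:
    def test_rule_all_passes_every_gene(self):
        genes = [f"g{i}" for i in range(7)]
        out = apply_selection_rule(study(genes, SelectionRule("all")))
        assert out == frozenset(genes)

    def test_fc_and_adj_p_rule_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        fc = rng.uniform(0.5, 5.0, 10)
        adj = rng.uniform(0.0, 0.2, 10)
        genes = [f"g{i}" for i in range(10)]
        out = apply_selection_rule(
            study(genes, SelectionRule("fc", 2.5, 0.05), fc=fc, adj_pvalue=adj)
        )
        # independent oracle: explicit row-by-row scan
        expected = {g for g, f, a in zip(genes, fc, adj) if f >= 2.5 and a <= 0.05}
        assert out == expected

    def test_empai_cutoff_is_strict(self):
        out = apply_selection_rule(
            study(["gA", "gB"], SelectionRule("empai", 1.0), empai=[1.0, 1.01])
        )
        assert out == {"gB"}

    def test_missing_statistic_column_is_error(self):
        with pytest.raises(ValueError, match="empai"):
            apply_selection_rule(study(["g1"], SelectionRule("empai", 1.0), fc=[2.0]))

    def test_duplicate_genes_deduplicated_before_rule(self):
        out = apply_selection_rule(
            study(["g1", "g1", "g2"], SelectionRule("fc", 2.0), fc=[3.0, 0.1, 3.0])
        )
        assert out == {"g1", "g2"}

    def test_rule_all_rejects_thresholds(self):
        with pytest.raises(ValueError):
            SelectionRule("all", threshold=1.0)


class TestCombine:
    def test_union_with_empty_set_is_identity(self):
        assert combine([{"a", "b"}, set()], "union") == {"a", "b"}

    def test_intersection_idempotent(self):
        s = frozenset({"a", "b", "c"})
        assert combine([s, s], "intersection") == s

    def test_union_then_intersection_matches_membership_enumeration(self):
        a, b, c = {"g1", "g2", "g3", "g4", "g5"}, {"g3", "g4", "g5", "g6", "g7"}, {"g1", "g4", "g5", "g8", "g9"}
        all_genes = a | b | c
        assert combine([a, b, c], "union") == {g for g in all_genes if g in a or g in b or g in c}
        assert combine([a, b, c], "intersection") == {g for g in all_genes if g in a and g in b and g in c}

    def test_single_input_returned_under_either_mode(self):
        s = {"x", "y"}
        assert combine([s], "union") == combine([s], "intersection") == s

    def test_empty_collection_is_error(self):
        with pytest.raises(ValueError):
            combine([], "union")

    @settings(deadline=None, derandomize=True)
    @given(genesets, genesets, genesets)
    def test_set_algebra_properties(self, a, b, c):
        assert combine([a, b], "union") == combine([b, a], "union")
        assert combine([combine([a, b], "union"), c], "union") == combine([a, combine([b, c], "union")], "union")
        # distributivity: a & (b | c) == (a & b) | (a & c)
        left = combine([a, combine([b, c], "union")], "intersection")
        right = combine([combine([a, b], "intersection"), combine([a, c], "intersection")], "union")
        assert left == right


class TestFinalize:
    def test_detection_filter_counts(self):
        universe = universe_from_counts(100, 10)
        genes = sorted(universe.gene_ids())[:20] + ["FBgn_nowhere1", "FBgn_nowhere2"]
        lst = finalize_against(genes, universe, "demo")
        assert lst.n_raw == 22 and lst.n_detected == 20
        assert lst.detected_members <= lst.raw_members

    def test_disjoint_list_has_zero_detected(self):
        universe = universe_from_counts(50, 5)
        lst = finalize_against({"gX", "gY"}, universe, "demo")
        assert lst.n_detected == 0

    def test_refinalizing_is_a_noop(self, universe1):
        genes = sorted(universe1.gene_ids())[:30]
        once = finalize_against(genes, universe1, "demo")
        again = finalize_against(once.detected_members, universe1, "demo")
        assert again.detected_members == once.detected_members
        assert again.n_detected == once.n_detected


class TestProteinMapping:
    def test_gene_with_one_of_two_isoforms_detected_contributes_one(self):
        protein_universe = universe_from_counts(1, 0, modality="protein")
        detected = next(iter(protein_universe.detected_keys()))
        idmap = IdMap(gene_to_proteins={"gA": frozenset({detected, "FBpp_missing"})})
        transcript_universe = universe_from_counts(3, 0)
        lst = finalize_against(
            set(list(transcript_universe.gene_ids())[:1]) | {"gA"}, transcript_universe, "demo"
        )
        plist = map_to_protein_universe(lst, idmap, protein_universe)
        assert plist.n_detected == 1

    def test_unmapped_gene_lookup_returns_empty_set(self):
        assert IdMap().proteins_of("gZ") == frozenset()

    def test_synthetic_map_matches_brute_force_join(self, truth1, universe1):
        idmap, protein_universe = generate_idmap(truth1, universe1)
        genes = sorted(universe1.gene_ids())[:200]
        lst = finalize_against(genes, universe1, "demo")
        plist = map_to_protein_universe(lst, idmap, protein_universe)
        # oracle: exhaustive (gene x map x universe) join
        expected = {
            prot
            for gene in lst.raw_members
            for prot in idmap.gene_to_proteins.get(gene, ())
            if prot in set(protein_universe.table.index)
        }
        assert plist.detected_members == expected

    def test_single_isoform_map_preserves_gene_counts(self, universe1):
        from listenrich import SyntheticTruth

        truth = SyntheticTruth(seed=3, isoform_lambda=1.0, protein_detect_rate=1.0)
        idmap, protein_universe = generate_idmap(truth, universe1)
        assert all(len(v) == 1 for v in idmap.gene_to_proteins.values())
        genes = sorted(universe1.gene_ids())[:50]
        lst = finalize_against(genes, universe1, "demo")
        plist = map_to_protein_universe(lst, idmap, protein_universe)
        assert plist.n_detected == lst.n_detected

    def test_wrong_modality_rejected(self, universe1):
        lst = finalize_against(sorted(universe1.gene_ids())[:5], universe1, "demo")
        with pytest.raises(ValueError, match="protein"):
            map_to_protein_universe(lst, IdMap(), universe1)


class TestCompileConfig:
    def test_yaml_compilation_applies_rules_and_combination(self, tmp_path):
        pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "fc": [3.0, 1.0, 3.0]}).to_csv(
            tmp_path / "a.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene_id": ["g3", "g4"], "log2fc": [1.0, 0.1], "adj_pvalue": [0.01, 0.01]}).to_csv(
            tmp_path / "b.tsv", sep="\t", index=False
        )
        (tmp_path / "lists.yaml").write_text(
            "lists:\n"
            "  - name: demo\n"
            "    combination: union\n"
            "    studies:\n"
            "      - {file: a.tsv, rule: {statistic: fc, threshold: 2.0}}\n"
            "      - {file: b.tsv, rule: {statistic: log2fc, threshold: 0.5, adj_p_max: 0.05}}\n"
        )
        compiled = compile_from_config(tmp_path / "lists.yaml")
        assert compiled["demo"] == ("union", frozenset({"g1", "g3"}))
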