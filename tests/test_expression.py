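"""RPKM, fold-change classification, mark grouping, Venn/crosstab
integration and term enrichment."""
from itertools import chain, combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftomics import expression as ex
from graftomics.errors import InputError


class TestRpkm:
    @pytest.mark.parametrize(
        "count, length, total, expected",
        [(0, 1000, 1e6, 0.0), (1000, 1000, 1e6, 1000.0), (50, 2000, 1e7, 2.5)],
    )
    def test_unit_arithmetic(self, count, length, total, expected):
        assert ex.rpkm(count, length, total) == pytest.approx(expected)

    def test_zero_length_or_total_is_an_error(self):
        with pytest.raises(InputError):
            ex.rpkm(10, 0, 1e6)
        with pytest.raises(InputError):
            ex.rpkm(10, 1000, 0)

    def test_matrix_matches_per_cell_oracle(self, rng):
        counts = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(30)],
             "s1": rng.integers(0, 5000, 30), "s2": rng.integers(0, 5000, 30)}
        )
        lengths = pd.Series(rng.integers(200, 3000, 30).astype(float),
                            index=counts["gene_id"])
        rp = ex.rpkm_matrix(counts, lengths)
        for col in ("s1", "s2"):
            total = counts[col].sum()
            for i in range(30):
                expected = ex.rpkm(counts[col][i], lengths.iloc[i], total)
                assert rp[col][i] == pytest.approx(expected, rel=1e-9)


class TestClassifyDeg:
    @pytest.mark.parametrize(
        "control, grafted, expected",
        [
            (20.5, 46.4, "up"),
            (151.4, 189.0, "nc"),
            (570.1, 264.3, "down"),
            (15.6, 42.7, "up"),
        ],
    )
    def test_worked_examples(self, control, grafted, expected):
        assert ex.classify_deg(control, grafted) == expected

    def test_threshold_is_inclusive_at_exactly_two(self):
        # a 1.9 -> 3.8 ratio is exactly 2.0 and classifies as up
        assert ex.classify_deg(1.9, 3.8, context_max_rpkm=21.2) == "up"

    def test_low_expression_is_filtered_on_the_context_max(self):
        assert ex.classify_deg(1.9, 3.8) == "filtered"
        assert ex.classify_deg(1.9, 3.8, context_max_rpkm=21.2) == "up"

    def test_zero_control_uses_the_epsilon_rescue(self):
        assert ex.classify_deg(0.0, 50.0, context_max_rpkm=50.0) == "up"

    def test_negative_rpkm_is_an_error(self):
        with pytest.raises(InputError):
            ex.classify_deg(-1.0, 5.0)


class TestMarkGroups:
    def _marks(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "k4", "k27", "dna"])

    def test_active_and_inactive_membership(self):
        marks = self._marks(
            [("a", "hyper", "none", "none"),   # K4 hyper -> active
             ("b", "none", "none", "both"),    # DNA both -> both groups
             ("c", "none", "none", "none"),    # unmarked -> neither
             ("d", "none", "hyper", "none"),   # K27 hyper -> inactive
             ("e", "hypo", "none", "hypo")]    # K4 hypo inactive + DNA hypo active
        )
        groups = ex.assign_mark_groups(marks)
        assert groups["active"] == {"a", "b", "e"}
        assert groups["inactive"] == {"b", "d", "e"}


class TestVenn:
    def test_disjoint_sets(self):
        sets = {"A": {1, 2}, "B": {3, 4, 5}, "C": {6, 7, 8, 9}}
        counts = ex.venn_counts(sets)
        assert counts[("A",)] == 2 and counts[("B",)] == 3 and counts[("C",)] == 4
        assert all(v == 0 for k, v in counts.items() if len(k) > 1)

    def test_identical_sets(self):
        s = set(range(5))
        counts = ex.venn_counts({"A": set(s), "B": set(s), "C": set(s)})
        assert counts[("A", "B", "C")] == 5
        assert sum(v for k, v in counts.items() if len(k) < 3) == 0

    def test_four_sets_unsupported(self):
        with pytest.raises(InputError):
            ex.venn_counts({c: set() for c in "ABCD"})

    @given(st.lists(st.sets(st.integers(0, 20)), min_size=3, max_size=3))
    @settings(max_examples=60, derandomize=True)
    def test_regions_match_power_set_oracle_and_partition_union(self, sets_list):
        sets = dict(zip("ABC", sets_list))
        counts = ex.venn_counts(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        # brute-force membership enumeration
        for elem in union:
            member = tuple(sorted(n for n in sets if elem in sets[n]))
            assert counts[member] >= 1


class TestCrosstab:
    def test_hand_computed_table(self):
        marks = pd.DataFrame(
            {"gene_id": ["a", "b", "c"],
             "k4": ["hyper", "none", "hypo"],
             "k27": ["none", "hyper", "none"],
             "dna": ["none", "both", "none"]}
        )
        deg = pd.Series({"a": "up", "b": "up", "c": "down"})
        tab = ex.crosstab_marks_by_deg(marks, deg)
        assert tab.loc["K4 hyper", "up"] == 1
        assert tab.loc["K4 hypo", "down"] == 1
        assert tab.loc["K27 hyper", "up"] == 1
        assert tab.loc["DNA hyper", "up"] == 1   # gene b via "both"
        assert tab.loc["DNA hypo", "up"] == 1
        assert tab.values.sum() == 5

    def test_matches_groupby_oracle(self, rng):
        n = 500
        marks = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)],
             "k4": rng.choice(["hyper", "hypo", "none"], n),
             "k27": rng.choice(["hyper", "hypo", "none"], n),
             "dna": rng.choice(["hyper", "hypo", "both", "none"], n)}
        )
        deg = pd.Series(rng.choice(["up", "down", "nc"], n),
                        index=marks["gene_id"])
        tab = ex.crosstab_marks_by_deg(marks, deg)
        for label, col in (("K4", "k4"), ("K27", "k27"), ("DNA", "dna")):
            for direction in ("hyper", "hypo"):
                sel = marks[col].isin([direction] + (["both"] if col == "dna" else []))
                for cls in ("up", "down"):
                    expected = int((deg.reindex(marks.loc[sel, "gene_id"]) == cls).sum())
                    assert tab.loc[f"{label} {direction}", cls] == expected

    def test_deg_label_swap_exchanges_columns(self, rng):
        marks = pd.DataFrame(
            {"gene_id": ["a", "b"], "k4": ["hyper", "hypo"],
             "k27": ["none", "none"], "dna": ["none", "none"]}
        )
        deg = pd.Series({"a": "up", "b": "down"})
        swapped = deg.map({"up": "down", "down": "up"})
        t1 = ex.crosstab_marks_by_deg(marks, deg)
        t2 = ex.crosstab_marks_by_deg(marks, swapped)
        assert (t1["up"] == t2["down"]).all() and (t1["down"] == t2["up"]).all()


def _hypergeom_oracle(N, K, n, k):
    """Exact over-representation tail by combinatorial enumeration."""
    return sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / comb(N, n)


class TestFisherEnrichment:
    def _term_map(self, assignment):
        rows = [{"gene_id": g, "term_id": t} for t, genes in assignment.items()
                for g in genes]
        return pd.DataFrame(rows)

    def test_whole_universe_term_is_never_enriched(self):
        universe = {f"g{i}" for i in range(10)}
        tm = self._term_map({"T1": universe})
        out = ex.fisher_term_enrichment({"g0", "g1"}, universe, tm)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_perfect_overlap_matches_the_combinatorial_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        out = ex.fisher_term_enrichment(set(term), universe, self._term_map({"T": term}))
        assert out["p_value"].iloc[0] == pytest.approx(1 / comb(20, 5), abs=1e-12)

    def test_empty_gene_set_gives_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        tm = self._term_map({"T": {"g0", "g1"}})
        out = ex.fisher_term_enrichment(set(), universe, tm)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(InputError):
            ex.fisher_term_enrichment(set(), set(), pd.DataFrame(columns=["gene_id", "term_id"]))

    def test_random_tables_match_oracle_to_1e10(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term = {f"g{i}" for i in range(K)}
            gene_set = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(gene_set & term)
            out = ex.fisher_term_enrichment(gene_set, universe, self._term_map({"T": term}))
            assert out["p_value"].iloc[0] == pytest.approx(
                _hypergeom_oracle(N, K, n, k), abs=1e-10)


class TestBuildTable1:
    def test_row_reconstruction_for_a_dna_hyper_gene(self):
        # a gene with 11 hyper DMPs, RPKM 12.1/4.7/5.3/7.7, classes Down/nc
        k4 = pd.DataFrame(columns=["gene_id", "signed_fold", "class"])
        k27 = pd.DataFrame(columns=["gene_id", "signed_fold", "class"])
        dmg = pd.DataFrame([{"gene_id": "gX", "n_hyper": 11, "n_hypo": 0,
                             "summary": "+11"}])
        expr = pd.DataFrame([{"gene_id": "gX", "rpkm_co_d0": 12.1, "rpkm_co_d3": 4.7,
                              "rpkm_gr_d0": 5.3, "rpkm_gr_d3": 7.7,
                              "class_d0": "down", "class_d3": "nc"}])
        out = ex.build_table1(k4, k27, dmg, expr)
        row = out.iloc[0]
        assert row["epigenetic_mark"] == "DNAmeth hyper"
        assert row["fold_enrichment_or_dmps"] == "+11"
        assert (row["fc_d0"], row["fc_d3"]) == ("down", "nc")

    def test_empty_inputs_give_header_only(self):
        empty = pd.DataFrame(columns=["gene_id", "signed_fold", "class"])
        dmg = pd.DataFrame(columns=["gene_id", "n_hyper", "n_hypo", "summary"])
        expr = pd.DataFrame(columns=["gene_id", "rpkm_co_d0", "rpkm_co_d3",
                                     "rpkm_gr_d0", "rpkm_gr_d3", "class_d0", "class_d3"])
        out = ex.build_table1(empty, empty, dmg, expr)
        assert len(out) == 0 and "epigenetic_mark" in out.columns

    def test_missing_expression_keeps_row_with_na(self):
        k4 = pd.DataFrame([{"gene_id": "gY", "signed_fold": 2.4, "class": "hyper"}])
        empty = pd.DataFrame(columns=["gene_id", "signed_fold", "class"])
        dmg = pd.DataFrame(columns=["gene_id", "n_hyper", "n_hypo", "summary"])
        expr = pd.DataFrame(columns=["gene_id", "rpkm_co_d0", "rpkm_co_d3",
                                     "rpkm_gr_d0", "rpkm_gr_d3", "class_d0", "class_d3"])
        out = ex.build_table1(k4, empty, dmg, expr)
        assert out.iloc[0]["fc_d0"] == "NA"
        assert out.iloc[0]["epigenetic_mark"] == "H3K4me3 hyper"
        assert out.iloc[0]["fold_enrichment_or_dmps"] == "2.4"

    def test_marked_genes_appear_exactly_once(self, rng):
        genes = [f"g{i}" for i in range(20)]
        k4 = pd.DataFrame({"gene_id": genes[:5], "signed_fold": 2.5, "class": "hyper"})
        k27 = pd.DataFrame({"gene_id": genes[3:8], "signed_fold": -2.5, "class": "hypo"})
        dmg = pd.DataFrame({"gene_id": genes[6:10], "n_hyper": 2, "n_hypo": 0,
                            "summary": "+2"})
        expr = pd.DataFrame(
            {"gene_id": genes, "rpkm_co_d0": 20.0, "rpkm_co_d3": 20.0,
             "rpkm_gr_d0": 50.0, "rpkm_gr_d3": 20.0,
             "class_d0": "up", "class_d3": "nc"}
        )
        out = ex.build_table1(k4, k27, dmg, expr)
        assert sorted(out["gene_id"]) == sorted(set(genes[:10]))
        assert out["gene_id"].is_unique
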