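"""Counting and Fisher's-exact enrichment against independent oracles."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from pathannot import (
    ContingencyInputs,
    InputError,
    Pathway,
    PathwayCollection,
    attach_icon,
    build_summary_table,
    count_annotated,
    fisher_enrichment_p,
    sort_table,
)
from pathannot.annotations import AnnotationRow, AnnotationSet, AnnotationTable
from conftest import hypergeom_tail_oracle


def _make_set(name, symbols, registry, icon="pill"):
    rows = tuple(AnnotationRow(s, (f"v{i}",)) for i, s in enumerate(symbols))
    table = AnnotationTable(name, ("Gene", "val"), rows, True)
    return attach_icon(table, icon, registry)


class TestFisherP:
    def test_k_zero_is_one(self):
        assert fisher_enrichment_p(ContingencyInputs(0, 5, 4, 10)) == 1.0

    def test_everything_annotated_is_one(self):
        assert fisher_enrichment_p(ContingencyInputs(4, 10, 4, 10)) == 1.0

    def test_perfect_overlap_small_case(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)/C(10,4) = 5/210, confirmed by
        # enumerating all 210 subsets
        p = fisher_enrichment_p(ContingencyInputs(4, 5, 4, 10))
        assert p == pytest.approx(5 / 210, rel=1e-12)
        assert p == pytest.approx(float(hypergeom_tail_oracle(4, 5, 4, 10)), rel=1e-12)

    @pytest.mark.parametrize("k,K,n,N", [
        (2, 4, 3, 9), (1, 2, 5, 8), (3, 6, 4, 11), (5, 5, 5, 10), (0, 0, 3, 7),
    ])
    def test_matches_subset_enumeration(self, k, K, n, N):
        expected = float(hypergeom_tail_oracle(k, K, n, N))
        assert fisher_enrichment_p(ContingencyInputs(k, K, n, N)) == \
            pytest.approx(expected, rel=1e-12)

    def test_cross_check_scipy_survival_function(self):
        # independent implementation route: hypergeom.sf(k-1, N, K, n)
        for (k, K, n, N) in [(3, 12, 8, 40), (10, 30, 25, 200), (1, 5, 9, 50)]:
            ours = fisher_enrichment_p(ContingencyInputs(k, K, n, N))
            ref = hypergeom.sf(k - 1, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_large_margins_stay_exact(self):
        # rational arithmetic must not lose precision at N ~ 1e4
        p = fisher_enrichment_p(ContingencyInputs(40, 200, 500, 10_000))
        ref = hypergeom.sf(39, 10_000, 200, 500)
        assert p == pytest.approx(ref, rel=1e-9)
        assert 0.0 < p < 1.0

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(k=5, K=3, n=10, N=20), "min"),
        (dict(k=0, K=25, n=10, N=20), "K"),
        (dict(k=0, K=5, n=30, N=20), "n"),
    ])
    def test_invariant_violations_named(self, kwargs, msg):
        with pytest.raises(InputError, match=msg):
            ContingencyInputs(**kwargs)

    @given(st.data())
    def test_monotone_in_k(self, data):
        N = data.draw(st.integers(2, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        ps = [fisher_enrichment_p(ContingencyInputs(k, K, n, N))
              for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    @given(st.data())
    def test_row_column_symmetry(self, data):
        N = data.draw(st.integers(2, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        a = fisher_enrichment_p(ContingencyInputs(k, K, n, N))
        b = fisher_enrichment_p(ContingencyInputs(k, n, K, N))
        assert a == pytest.approx(b, rel=1e-12)

    def test_p_one_at_minimum_support_point(self):
        # lo = max(0, n-(N-K)) > 0: overlap cannot be smaller than lo
        c = ContingencyInputs(k=2, K=6, n=6, N=10)  # lo = 2
        assert fisher_enrichment_p(c) == 1.0


class TestCounts:
    def test_disjoint_zero(self, registry):
        pw = Pathway("p", "p", "t", frozenset({"A", "B"}))
        assert count_annotated(pw, _make_set("s", ["X", "Y"], registry)) == 0

    def test_saturation(self, registry):
        pw = Pathway("p", "p", "t", frozenset({"A", "B"}))
        s = _make_set("s", ["A", "B", "C"], registry)
        assert count_annotated(pw, s) == pw.n_genes

    def test_duplicates_collapse_to_genes(self, registry):
        pw = Pathway("p", "p", "t", frozenset({"A", "B", "C", "D"}))
        s = _make_set("s", ["A", "A", "C", "X"], registry)
        assert count_annotated(pw, s) == 2


class TestSummaryTable:
    @pytest.fixture
    def table(self, tiny_collection, registry):
        sets = [
            _make_set("mut", ["TP53", "TP53", "KRAS", "CDK4"], registry),
            _make_set("drug", ["MYC", "CDK6"], registry, icon="star"),
        ]
        return build_summary_table(tiny_collection, sets, with_enrichment=True)

    def test_counts_match_brute_force(self, table, tiny_collection, registry):
        sets = {"mut": {"TP53", "KRAS", "CDK4"}, "drug": {"MYC", "CDK6"}}
        for row in table.rows:
            pw = next(p for p in tiny_collection if p.id == row.pathway_id)
            for name, genes in sets.items():
                assert row.counts[name] == len(pw.genes & genes)

    def test_p_values_recomputed_from_margins(self, table, tiny_collection):
        N = len(tiny_collection.universe)
        for row in table.rows:
            for name, K in (("mut", 3), ("drug", 2)):
                expected = float(hypergeom_tail_oracle(
                    row.counts[name], K, row.n_genes, N))
                assert row.p_values[name] == pytest.approx(expected, rel=1e-12)

    def test_empty_set_counts_zero_p_one(self, tiny_collection, registry):
        with pytest.warns(UserWarning, match="no genes"):
            t = build_summary_table(
                tiny_collection, [_make_set("none", [], registry)],
                with_enrichment=True)
        assert all(r.counts["none"] == 0 and r.p_values["none"] == 1.0
                   for r in t.rows)

    def test_empty_collection_is_error(self, registry):
        with pytest.raises(InputError):
            build_summary_table(PathwayCollection([]), [])

    def test_bh_adjustment_bounds_and_order(self, table, tiny_collection, registry):
        sets = [_make_set("mut", ["TP53", "KRAS", "CDK4"], registry)]
        t = build_summary_table(tiny_collection, sets,
                                with_enrichment=True, adjust="bh")
        for r in t.rows:
            assert r.p_adjusted["mut"] >= r.p_values["mut"] - 1e-15
            assert 0.0 <= r.p_adjusted["mut"] <= 1.0

    def test_to_frame_columns(self, table):
        df = table.to_frame()
        assert list(df.columns[:4]) == ["pathway_id", "name", "source", "n_genes"]
        assert "mut_count" in df.columns and "drug_p" in df.columns


class TestSort:
    def test_sort_idempotent(self, tiny_collection, registry):
        t = build_summary_table(tiny_collection,
                                [_make_set("s", ["TP53"], registry)])
        once = sort_table(t, "n_genes", "desc")
        twice = sort_table(once, "n_genes", "desc")
        assert [r.pathway_id for r in once.rows] == [r.pathway_id for r in twice.rows]
        assert twice.sort_state == ("n_genes", "desc")

    def test_distinct_keys_reverse_exactly(self, tiny_collection, registry):
        t = build_summary_table(tiny_collection,
                                [_make_set("s", ["TP53", "MYC"], registry)])
        asc = sort_table(t, "pathway_id", "asc")
        desc = sort_table(t, "pathway_id", "desc")
        assert [r.pathway_id for r in desc.rows] == \
            [r.pathway_id for r in asc.rows][::-1]

    def test_ties_keep_original_order(self, registry):
        collection = PathwayCollection([
            Pathway(f"p{i}", f"P{i}", "t", frozenset({"A"})) for i in range(4)])
        t = build_summary_table(collection, [_make_set("s", ["A"], registry)])
        s = sort_table(t, "s_count", "desc")  # all counts equal
        assert [r.pathway_id for r in s.rows] == ["p0", "p1", "p2", "p3"]

    def test_p_value_sort_matches_extracted_column(self, tiny_collection, registry):
        t = build_summary_table(
            tiny_collection, [_make_set("s", ["TP53", "KRAS"], registry)],
            with_enrichment=True)
        s = sort_table(t, "s_p", "asc")
        ps = [r.p_values["s"] for r in s.rows]
        assert ps == sorted(ps)

    def test_unknown_column_is_error(self, tiny_collection, registry):
        t = build_summary_table(tiny_collection, [])
        with pytest.raises(InputError, match="bogus"):
            sort_table(t, "bogus")
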