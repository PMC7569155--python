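"""Hypergeometric/EASE tails, BH adjustment, over-representation runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.enrichment import (
    benjamini_hochberg,
    ease_tail,
    enrich_gene_set,
    hypergeometric_tail,
)
from netpharm.io import AnnotationTable
from netpharm.refdata import PATHWAY_KEY_TARGETS, key_target_union
from netpharm.synthetic import SyntheticScenario, gen_annotations
from conftest import annotation_table_from_df
from oracles import bh_stepup, hypergeom_tail_enum


@st.composite
def hypergeom_params(draw):
    N = draw(st.integers(min_value=1, max_value=40))
    K = draw(st.integers(min_value=0, max_value=N))
    n = draw(st.integers(min_value=0, max_value=N))
    k = draw(st.integers(min_value=0, max_value=min(K, n)))
    return k, K, n, N


class TestHypergeometricTail:
    def test_zero_overlap_is_exactly_one(self):
        assert hypergeometric_tail(0, 5, 4, 10) == 1.0

    def test_full_overlap_small_case_matches_enumeration(self):
        # drawing 4 of 10 with 5 marked: all-marked draws are C(5,4)=5 of C(10,4)=210
        assert hypergeometric_tail(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    @given(hypergeom_params())
    @settings(max_examples=150, deadline=None)
    def test_matches_pmf_summation_oracle(self, params):
        k, K, n, N = params
        assert hypergeometric_tail(k, K, n, N) == pytest.approx(
            hypergeom_tail_enum(k, K, n, N), rel=1e-10, abs=1e-12
        )

    @given(hypergeom_params())
    @settings(max_examples=100, deadline=None)
    def test_tail_decreases_as_overlap_grows(self, params):
        k, K, n, N = params
        if k + 1 <= min(K, n):
            assert hypergeometric_tail(k + 1, K, n, N) <= hypergeometric_tail(
                k, K, n, N
            )

    @given(hypergeom_params())
    @settings(max_examples=100, deadline=None)
    def test_ease_is_at_least_plain_tail(self, params):
        k, K, n, N = params
        if k >= 1:
            assert ease_tail(k, K, n, N) >= hypergeometric_tail(k, K, n, N)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 4, 4, 10)
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 11, 4, 10)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == [pytest.approx(0.03)]

    def test_equally_spaced_collapse_to_largest(self):
        # step-up: min_j>=i p_(j) m/j = 0.04 for every rank
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(
            st.floats(min_value=1e-8, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_recurrence_and_dominates_raw(self, ps):
        adj = benjamini_hochberg(ps)
        oracle = bh_stepup(ps)
        assert adj == pytest.approx(oracle, rel=1e-12, abs=1e-12)
        assert all(a >= p - 1e-15 and a <= 1.0 for a, p in zip(adj, ps))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])


def _table(terms):
    return AnnotationTable(
        {tid: (tid, frozenset(genes)) for tid, genes in terms.items()}
    )


class TestEnrichGeneSet:
    def test_disjoint_query_yields_empty_result(self):
        table = _table({"T1": {"A", "B"}, "T2": {"C"}})
        assert enrich_gene_set({"X", "Y"}, table, background={"A", "B", "C", "X", "Y"}) == []

    def test_planted_term_ranks_first_and_p_matches_enumeration(self):
        rng = np.random.default_rng(2)
        background = {f"G{i}" for i in range(1000)}
        query = set(rng.choice(sorted(background), 20, replace=False))
        planted = set(rng.choice(sorted(query), 16, replace=False)) | set(
            rng.choice(sorted(background - query), 10, replace=False)
        )
        decoys = {
            f"D{j}": set(rng.choice(sorted(background), 30, replace=False))
            for j in range(10)
        }
        table = _table({"PLANTED": planted, **decoys})
        results = enrich_gene_set(query, table, background=background)
        assert results[0].term_id == "PLANTED"
        r = results[0]
        assert r.p_raw == pytest.approx(
            hypergeom_tail_enum(r.k, r.K, r.n, r.N), rel=1e-9
        )

    def test_key_target_fixture_reports_exact_overlap_for_p53_row(self):
        """On the bundled pathway fixture, the p53-signaling row's overlap
        is exactly its eight annotated key targets."""
        padding = {f"PAD{i}" for i in range(60)}  # annotated, never queried
        table = AnnotationTable(
            {
                tid: (name, frozenset(genes) | frozenset(list(padding)[:5]))
                for tid, (name, genes) in PATHWAY_KEY_TARGETS.items()
            }
        )
        query = key_target_union()
        results = enrich_gene_set(query, table, background=key_target_union() | padding)
        by_id = {r.term_id: r for r in results}
        assert set(by_id["hsa04115"].overlap_genes) == {
            "CASP3", "RRM2", "BAX", "CASP8", "TP53", "MDM2", "RRM2B", "APAF1"
        }

    def test_query_genes_outside_background_are_dropped(self):
        table = _table({"T1": {"A", "B", "C"}})
        res = enrich_gene_set({"A", "ZZZ"}, table, background={"A", "B", "C", "D"})
        assert res[0].n == 1 and res[0].k == 1

    def test_results_sorted_by_p_then_term_id(self):
        sc = SyntheticScenario(seed=8)
        df, truth = gen_annotations(sc)
        res = enrich_gene_set(
            truth["query_genes"], annotation_table_from_df(df),
            background=truth["background"],
        )
        keys = [(r.p_raw, r.term_id) for r in res]
        assert keys == sorted(keys)
        assert all(r.p_adj >= r.p_raw for r in res)
        assert all(r.k <= min(r.K, r.n) for r in res)

    def test_empty_background_is_fatal(self):
        with pytest.raises(ValueError, match="background"):
            enrich_gene_set({"A"}, _table({"T1": {"A"}}), background=set())

    def test_ease_variant_never_more_significant(self):
        sc = SyntheticScenario(seed=9)
        df, truth = gen_annotations(sc)
        table = annotation_table_from_df(df)
        hyp = {
            r.term_id: r.p_raw
            for r in enrich_gene_set(
                truth["query_genes"], table, background=truth["background"]
            )
        }
        ease = {
            r.term_id: r.p_raw
            for r in enrich_gene_set(
                truth["query_genes"], table,
                background=truth["background"], method="ease",
            )
        }
        assert set(hyp) == set(ease)
        assert all(ease[t] >= hyp[t] for t in hyp)

    def test_null_false_positive_rate_is_controlled(self):
        """With a uniformly drawn query the fraction of term tests
        reaching p < 0.05 stays below 0.05 plus sampling error; the
        discrete tail is conservative, so no lower bound is asserted."""
        rng = np.random.default_rng(12)
        N, nq, n_terms, reps = 400, 25, 20, 60
        background = [f"G{i}" for i in range(N)]
        terms = {
            f"T{j}": set(rng.choice(background, int(rng.integers(20, 50)), replace=False))
            for j in range(n_terms)
        }
        table = _table(terms)
        hits = 0
        total = reps * n_terms
        for _ in range(reps):
            query = set(rng.choice(background, nq, replace=False))
            res = enrich_gene_set(query, table, background=set(background),
                                  correction="none")
            hits += sum(r.p_raw < 0.05 for r in res)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se
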