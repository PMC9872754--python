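"""Over-representation, term filtering, enrichment maps and linkage coverage."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from enscompare.enrichment import (
    GeneSet,
    GeneSetDB,
    build_enrichment_map,
    cross_species_match,
    enrich_fisher,
    filter_specific_terms,
    highlight_terms,
    involvement_fraction,
    linkage_coverage,
    select_go_level,
)
from enscompare.orthologs import ORTHOLOG_COLUMNS, OrthologTable, filter_high_quality


def hypergeom_oracle(N, K, n, k):
    """Upper-tail p by exhaustive enumeration over all C(N, n) draws."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


class TestEnrichFisher:
    def test_term_without_background_genes_gets_p_one(self):
        db = GeneSetDB([GeneSet("t1", genes={"outside"})])
        with pytest.warns(UserWarning, match="no genes"):
            res = enrich_fisher({"g1"}, {"g1", "g2"}, db)
        assert res.loc["t1", "p"] == 1.0

    def test_matches_enumeration_oracle_reduced_instance(self):
        # N=10 background, K=4 term genes, n=4 DEGs, k = observed overlap
        background = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(4)}
        deg = {"g0", "g1", "g5", "g6"}  # overlap k=2
        db = GeneSetDB([GeneSet("t", genes=term)])
        res = enrich_fisher(deg, background, db)
        assert res.loc["t", "p"] == pytest.approx(hypergeom_oracle(10, 4, 4, 2))

    def test_q_partition_equals_bh_at_level(self, rng):
        genes = [f"g{i}" for i in range(40)]
        background = set(genes)
        deg = set(genes[:10])
        db = GeneSetDB(
            [
                GeneSet(f"t{j}", genes=set(rng.choice(genes, 8, replace=False)))
                for j in range(20)
            ]
        )
        res = enrich_fisher(deg, background, db)
        from statsmodels.stats.multitest import multipletests

        reject, q, _, _ = multipletests(res["p"], alpha=0.05, method="fdr_bh")
        assert ((res["q"] < 0.05) == reject).all()

    def test_deg_outside_background_rejected(self):
        db = GeneSetDB([GeneSet("t", genes={"g1"})])
        with pytest.raises(ValueError, match="background"):
            enrich_fisher({"zzz"}, {"g1"}, db)


class TestFilterSpecificTerms:
    def make(self, level, overlap, associated):
        db = GeneSetDB(
            [
                GeneSet(
                    "t",
                    go_level=level,
                    genes={f"g{i}" for i in range(associated)},
                    associated_gene_count=associated,
                )
            ]
        )
        res = pd.DataFrame(
            {"overlap_count": [overlap], "p": [0.01], "q": [0.02]}, index=["t"]
        )
        return res, db

    @pytest.mark.parametrize(
        "level,overlap,associated,kept",
        [
            (6, 3, 5, False),  # below the specific level band
            (8, 3, 5, True),  # 0.6 > 0.5
            (8, 1, 2, False),  # 0.5 is not > 0.5
            (16, 3, 5, False),  # above the band
            (7, 1, 1, True),  # minimum genes/term = 1 suffices
        ],
    )
    def test_level_and_mapped_fraction_rules(self, level, overlap, associated, kept):
        res, db = self.make(level, overlap, associated)
        out = filter_specific_terms(res, db)
        assert ("t" in out.index) == kept

    def test_missing_level_excluded_with_warning(self):
        res, db = self.make(None, 3, 5)
        with pytest.warns(UserWarning, match="lack a GO level"):
            out = filter_specific_terms(res, db)
        assert len(out) == 0


class TestSelectGoLevel:
    def mk(self, n_sig):
        qs = [0.01] * n_sig + [0.5] * 2
        return pd.DataFrame({"q": qs})

    def test_first_level_meeting_rule(self):
        by_level = {7: self.mk(1), 8: self.mk(3), 9: self.mk(5)}
        assert select_go_level(by_level) == 8

    def test_no_level_qualifies(self):
        assert select_go_level({7: self.mk(0), 8: self.mk(0)}) is None

    def test_min_bps_one_takes_minimum_level(self):
        by_level = {7: self.mk(1), 8: self.mk(3)}
        assert select_go_level(by_level, min_bps=1) == 7


class TestBuildEnrichmentMap:
    def test_identical_sets_linked_with_coefficient_one(self):
        terms = [GeneSet("a", genes={"g1", "g2"}), GeneSet("b", genes={"g1", "g2"})]
        emap = build_enrichment_map(terms)
        assert emap.graph.edges["a", "b"]["overlap_coefficient"] == 1.0

    def test_hand_computed_coefficient_and_shared_count(self):
        terms = [
            GeneSet("a", genes={"g1", "g2", "g3", "g4"}),
            GeneSet("b", genes={"g1", "g2", "x1", "x2", "x3", "x4", "x5", "x6"}),
        ]
        emap = build_enrichment_map(terms, overlap_cutoff=0.25)
        e = emap.graph.edges["a", "b"]
        assert e["overlap_coefficient"] == pytest.approx(0.5)
        assert e["shared_gene_count"] == 2

    def test_disjoint_sets_not_linked(self):
        terms = [GeneSet("a", genes={"g1"}), GeneSet("b", genes={"g2"})]
        assert build_enrichment_map(terms).graph.number_of_edges() == 0

    def test_edges_stable_under_input_ordering(self, toy_terms):
        e1 = set(build_enrichment_map(toy_terms).graph.edges)
        e2 = set(build_enrichment_map(toy_terms[::-1]).graph.edges)
        assert {frozenset(e) for e in e1} == {frozenset(e) for e in e2}

    def test_sub_cutoff_overlap_not_linked(self):
        terms = [
            GeneSet("a", genes={f"g{i}" for i in range(10)}),
            GeneSet("b", genes={"g0"} | {f"x{i}" for i in range(9)}),
        ]
        emap = build_enrichment_map(terms, overlap_cutoff=0.25)
        assert emap.graph.number_of_edges() == 0  # coefficient 0.1


class TestHighlightAndCoverage:
    @pytest.fixture()
    def toy_map(self):
        # nodes n1,n2,n3 with member DEGs {g1},{g2},{g1,g3};
        # edges (n1,n2,shared=2) and (n2,n3,shared=3)
        terms = [
            GeneSet("n1", genes={"g1", "s1", "s2", "u1", "u2"}),
            GeneSet("n2", genes={"g2", "s1", "s2", "t1", "t2", "t3"}),
            GeneSet("n3", genes={"g1", "g3", "t1", "t2", "t3"}),
        ]  # n1-n3 share only g1: coefficient 1/5 stays under the cutoff
        emap = build_enrichment_map(
            terms, overlap_cutoff=0.25, deg_genes={"g1", "g2", "g3"}
        )
        assert emap.graph.edges["n1", "n2"]["shared_gene_count"] == 2
        assert emap.graph.edges["n2", "n3"]["shared_gene_count"] == 3
        return emap

    def test_highlight_by_membership(self, toy_map):
        assert highlight_terms(toy_map, {"g1"}) == {"n1", "n3"}
        assert highlight_terms(toy_map, set()) == set()
        assert highlight_terms(toy_map, {"g1", "g2", "g3"}) == {"n1", "n2", "n3"}

    def test_self_coverage_is_one_both_modes(self, toy_map):
        ref = {"g1", "g2", "g3"}
        for mode in ("weight", "edge"):
            assert (
                linkage_coverage(toy_map, ref, ref, mode=mode).linkage_coverage == 1.0
            )

    def test_empty_subset_covers_nothing(self, toy_map):
        rep = linkage_coverage(toy_map, set(), {"g1", "g2", "g3"})
        assert rep.linkage_coverage == 0.0

    def test_hand_counted_partial_coverage(self, toy_map):
        # subset {g1,g2} highlights {n1,n2,n3}? no: g1 in n1,n3; g2 in n2 ->
        # all three highlighted. Use {g2,g3}: highlights n2 and n3 only ->
        # covered edge (n2,n3) weight 3 of total 5, edges 1 of 2
        sub = {"g2", "g3"}
        ref = {"g1", "g2", "g3"}
        assert linkage_coverage(toy_map, sub, ref, mode="edge").linkage_coverage == 0.5
        assert (
            linkage_coverage(toy_map, sub, ref, mode="weight").linkage_coverage
            == pytest.approx(3 / 5)
        )

    def test_endpoint_rule_any_is_more_permissive(self, toy_map):
        sub = {"g2"}  # highlights only n2
        both = linkage_coverage(toy_map, sub, {"g1", "g2", "g3"}, endpoint_rule="both")
        any_ = linkage_coverage(toy_map, sub, {"g1", "g2", "g3"}, endpoint_rule="any")
        assert both.covered_edge_count == 0
        assert any_.covered_edge_count == 2

    def test_zero_reference_coverage_is_an_error(self, toy_map):
        with pytest.raises(ValueError, match="reference"):
            linkage_coverage(toy_map, {"g1"}, set())

    def test_coverage_monotone_under_subset_growth(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(25):
            terms = [
                GeneSet(f"t{j}", genes=set(rng.choice(genes, 8, replace=False)))
                for j in range(8)
            ]
            emap = build_enrichment_map(terms, 0.25, deg_genes=set(genes))
            ref = set(genes)
            small = set(rng.choice(genes, 5, replace=False))
            big = small | set(rng.choice(genes, 10, replace=False))
            try:
                for mode in ("weight", "edge"):
                    c_small = linkage_coverage(emap, small, ref, mode=mode)
                    c_big = linkage_coverage(emap, big, ref, mode=mode)
                    assert c_small.linkage_coverage <= c_big.linkage_coverage + 1e-12
            except ValueError:
                continue  # edgeless map: reference covers nothing


class TestInvolvementFraction:
    def test_printed_worked_example_rounds_to_43(self):
        assert round(involvement_fraction(47, 135, 48, 86)) == 43

    def test_full_highlighting_gives_100(self):
        assert involvement_fraction(10, 10, 5, 5) == 100.0

    def test_half_highlighting(self):
        assert involvement_fraction(1, 2, 1, 2) == 50.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            involvement_fraction(0, 0, 0, 0)

    def test_highlighted_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            involvement_fraction(3, 2, 0, 1)


class TestCrossSpeciesMatch:
    @pytest.fixture()
    def bijection(self):
        rows = [(f"a{i}", f"b{i}", "one2one", 90, 90) for i in range(10)]
        return filter_high_quality(
            OrthologTable(pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS))
        )

    @pytest.fixture()
    def native_map(self):
        terms = [
            GeneSet("n1", genes={"a1", "s1", "s2"}),
            GeneSet("n2", genes={"a2", "s1", "s2"}),
        ]
        return build_enrichment_map(terms, 0.25, deg_genes={"a1", "a2"})

    def test_image_of_native_degs_gives_full_coverage(self, bijection, native_map):
        rep = cross_species_match(
            native_map, {"b1", "b2"}, bijection, {"a1", "a2"}, direction="b_to_a"
        )
        assert rep.linkage_coverage == 1.0

    def test_unmappable_foreign_set_covers_nothing(self, bijection, native_map):
        with pytest.warns(UserWarning, match="no foreign DEG"):
            rep = cross_species_match(
                native_map, {"zz1"}, bijection, {"a1", "a2"}, direction="b_to_a"
            )
        assert rep.linkage_coverage == 0.0

    def test_few_driver_genes_can_cover_everything(self, bijection):
        # a small foreign set hitting every term covers all linkages even
        # though it is much smaller than the native DEG list
        native_degs = {f"a{i}" for i in range(10)}
        terms = [
            GeneSet("t1", genes={"a1", "a3", "a4", "c1", "c2"}),
            GeneSet("t2", genes={"a1", "a5", "a6", "c1", "c2"}),
            GeneSet("t3", genes={"a1", "a7", "a8", "c2", "c3"}),
        ]
        emap = build_enrichment_map(terms, 0.25, deg_genes=native_degs)
        rep = cross_species_match(
            emap, {"b1"}, bijection, native_degs, direction="b_to_a"
        )
        assert rep.linkage_coverage == 1.0
        assert rep.highlighted_node_count == 3


def test_hypergeom_matches_oracle_on_spot_instances():
    from scipy import stats

    for (N, K, n, k) in [(10, 4, 4, 2), (8, 3, 5, 1), (12, 6, 6, 3), (6, 2, 2, 2)]:
        assert stats.hypergeom.sf(k - 1, N, K, n) == pytest.approx(
            hypergeom_oracle(N, K, n, k), rel=1e-12
        )
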