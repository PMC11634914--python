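"""Compendium construction and enrichment statistics."""

import math
from itertools import combinations

import numpy as np
import pytest

from pmfvar import interactome_matrisome as im
from pmfvar.io_formats import (
    GeneAnnotation,
    InteractionEdge,
    InteractionSource,
    MatrisomeDivision,
    Staining,
)


def biogrid_edge(a, b, n_pubs=2, system="physical"):
    return InteractionEdge.make(a, b, InteractionSource.BIOGRID, system, n_pubs)


def annotation(gene, staining=Staining.MISSING,
               division=MatrisomeDivision.NON_MATRISOME, category="none"):
    return GeneAnnotation(gene, division, category, staining)


class TestCompendium:
    def test_query_without_edges_has_empty_set(self):
        comp = im.build_compendium([biogrid_edge("A", "B")], ["WNT8B"], {})
        assert comp.partners("WNT8B") == {}

    def test_single_publication_physical_edge_excluded(self):
        comp = im.build_compendium([biogrid_edge("CAPN1", "ACTC1", n_pubs=1)], ["CAPN1"], {})
        assert comp.partners("CAPN1") == {}

    def test_genetic_edges_excluded_regardless_of_support(self):
        comp = im.build_compendium(
            [biogrid_edge("CAPN1", "ACTC1", n_pubs=5, system="genetic")], ["CAPN1"], {})
        assert comp.partners("CAPN1") == {}

    def test_pairlist_edges_exempt_from_multivalidation(self):
        edge = InteractionEdge.make("UNC45A", "HSP90AA1", InteractionSource.HURI, "physical", 1)
        comp = im.build_compendium([edge], ["UNC45A"], {})
        assert set(comp.partners("UNC45A")) == {"HSP90AA1"}

    def test_self_loops_dropped(self):
        comp = im.build_compendium([biogrid_edge("CAPN1", "CAPN1")], ["CAPN1"], {})
        assert comp.partners("CAPN1") == {}

    def test_planted_heart_enhanced_partner_count_recovered(self):
        """A fixture with 32 planted heart-enhanced partners yields exactly
        that heart-enhanced interactor set."""
        partners = [f"P{i:02d}" for i in range(40)]
        edges = [biogrid_edge("CAPN1", p) for p in partners]
        ann = {p: annotation(p, Staining.HIGH if i < 20 else
                             (Staining.MEDIUM if i < 32 else Staining.LOW))
               for i, p in enumerate(partners)}
        comp = im.build_compendium(edges, ["CAPN1"], ann)
        enhanced, n_missing = im.heart_enhanced_interactions(comp, "CAPN1")
        assert len(enhanced) == 32
        assert n_missing == 0

    def test_missing_staining_excluded_but_tallied(self):
        edges = [biogrid_edge("Q", "A"), biogrid_edge("Q", "B")]
        ann = {"A": annotation("A", Staining.HIGH)}
        comp = im.build_compendium(edges, ["Q"], ann)
        enhanced, n_missing = im.heart_enhanced_interactions(comp, "Q")
        assert enhanced == {"A"} and n_missing == 1

    def test_rebuild_from_own_edges_is_fixed_point(self):
        edges = [biogrid_edge("Q", p) for p in ("A", "B", "C")]
        comp1 = im.build_compendium(edges, ["Q"], {})
        rebuilt_edges = [
            InteractionEdge.make("Q", sym, it.source, "physical", it.n_supporting_publications)
            for sym, it in comp1.partners("Q").items()]
        comp2 = im.build_compendium(rebuilt_edges, ["Q"], {})
        assert set(comp2.partners("Q")) == set(comp1.partners("Q"))


class TestChiSquare:
    BACKGROUND = {f"g{i}": ("core_matrisome" if i < 30 else "matrisome_associated")
                  for i in range(100)}

    def test_observed_proportional_to_background_gives_zero_statistic(self):
        observed = {f"g{i}": "core_matrisome" for i in range(3)}
        observed.update({f"h{i}": "matrisome_associated" for i in range(7)})
        res = im.chisq_category_test(observed, self.BACKGROUND, "division")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_formula_on_two_categories(self):
        observed = {f"g{i}": "core_matrisome" for i in range(8)}
        observed.update({f"h{i}": "matrisome_associated" for i in range(2)})
        res = im.chisq_category_test(observed, self.BACKGROUND, "division")
        expected_core, expected_assoc = 3.0, 7.0
        hand = (8 - expected_core) ** 2 / expected_core + (2 - expected_assoc) ** 2 / expected_assoc
        assert res.statistic == pytest.approx(hand, abs=1e-9)
        from scipy.stats import chi2
        assert res.p_value == pytest.approx(float(chi2.sf(hand, 1)))

    def test_statistic_invariant_under_category_relabeling(self):
        observed = {"a": "x", "b": "x", "c": "y"}
        bg = {f"u{i}": "x" for i in range(10)} | {f"v{i}": "y" for i in range(30)}
        res1 = im.chisq_category_test(observed, bg, "family")
        relabel = {"x": "y", "y": "x"}
        res2 = im.chisq_category_test({k: relabel[v] for k, v in observed.items()},
                                      {k: relabel[v] for k, v in bg.items()}, "family")
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_degenerate_single_category_p_one(self):
        res = im.chisq_category_test({"a": "x"}, {"u": "x", "v": "x"}, "family")
        assert res.p_value == 1.0 and res.statistic is None

    def test_null_calibration_on_planted_uniform_sets(self):
        """Gene sets drawn from the background reject at ~alpha."""
        rng = np.random.default_rng(2024)
        bg_genes = list(self.BACKGROUND)
        hits = 0
        reps = 1000
        for _ in range(reps):
            picked = rng.choice(bg_genes, size=30, replace=False)
            observed = {g: self.BACKGROUND[g] for g in picked}
            res = im.chisq_category_test(observed, self.BACKGROUND, "division")
            hits += res.p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        # chi-square on discrete counts is approximate; allow 4 MC sigma
        assert hits / reps < 0.05 + 4 * se


def hypergeom_tail_by_enumeration(k, K, n, N):
    """P(X >= k) by direct combinatorial sum — independent oracle."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestHypergeometric:
    def test_zero_successes_tail_is_one(self):
        assert im.hypergeom_enrichment(0, 5, 4, 20).p_value == 1.0

    def test_all_three_of_three_from_ten(self):
        res = im.hypergeom_enrichment(3, 3, 3, 10)
        assert res.p_value == pytest.approx(1 / 120, rel=1e-12)

    def test_two_of_four_against_five_in_twenty(self):
        res = im.hypergeom_enrichment(2, 5, 4, 20)
        assert res.p_value == pytest.approx(1205 / 4845, rel=1e-12)

    def test_parameter_violations_rejected(self):
        with pytest.raises(ValueError):
            im.hypergeom_enrichment(5, 3, 4, 10)
        with pytest.raises(ValueError):
            im.hypergeom_enrichment(1, 3, 11, 10)

    def test_exhaustive_agreement_with_enumeration_below_n12(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert im.hypergeom_enrichment(k, K, n, N).p_value == pytest.approx(
                            hypergeom_tail_by_enumeration(k, K, n, N), rel=1e-9, abs=1e-12)

    def test_tail_monotone_nonincreasing_in_k(self):
        K, n, N = 30, 40, 100
        ps = [im.hypergeom_enrichment(k, K, n, N).p_value for k in range(min(K, n) + 1)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_far_tail_resolves_below_1e16(self):
        # log-space internals keep extreme enrichment p-values exact
        res = im.hypergeom_enrichment(200, 300, 250, 1000)
        assert 0 < res.p_value < 1e-16


class TestHeartEnrichmentEndToEnd:
    def test_background_is_staining_annotated_universe(self):
        ann = {f"P{i}": annotation(f"P{i}", Staining.HIGH if i < 30 else Staining.LOW)
               for i in range(100)}
        ann["Q"] = annotation("Q")
        edges = [biogrid_edge("Q", f"P{i}") for i in range(25)]  # 25 enhanced partners
        comp = im.build_compendium(edges, ["Q"], ann)
        res = im.heart_enrichment_test(comp, ann)
        assert res.observed == {"k": 25, "n": 25}
        assert res.expected == {"K": 30, "N": 100}
        assert res.p_value == pytest.approx(
            hypergeom_tail_by_enumeration(25, 30, 25, 100), rel=1e-9)
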