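"""Matching engine: relation degrees, greedy matching, Jaro-Winkler, score."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semfood.cme import (
    MatchConfig,
    Relation,
    classify_relation,
    evaluate,
    greedy_match,
    intolerance_score,
    jaro,
    pair_term,
    percentage,
    winkler,
)
from semfood.ontology import graph_from_dict


class TestClassifyRelation:
    @pytest.mark.parametrize(
        "c,p,relation,weight,distance",
        [
            ("Vitamin B3", "Niacin", Relation.EXACT, 1.0, 1),
            ("Algin", "Alginic Acid", Relation.EXACT, 1.0, 1),
            ("Algin", "Algin", Relation.EXACT, 1.0, 0),
            ("D-Isoascorbic Acid", "Ascorbic Acid", Relation.SUBSUME, 1 / 3, 1),
            ("Algin", "Sodium Alginate", Relation.PLUGIN, 1 / 2, 1),
            ("D-Isoascorbic Acid", "Ascorbyl Palmitate", Relation.SUBSUME, 1 / 9, 2),
            ("Vitamin C", "Folic Acid", Relation.DISSIMILAR, 0.0, None),
        ],
    )
    def test_example_mode(self, graph, example_cfg, c, p, relation, weight, distance):
        rel, w, d = classify_relation(graph, c, p, example_cfg)
        assert rel is relation
        assert w == pytest.approx(weight)
        assert d == distance

    def test_definition_mode_swaps_hierarchy_directions(self, graph, definition_cfg):
        rel, w, d = classify_relation(graph, "D-Isoascorbic Acid", "Ascorbic Acid", definition_cfg)
        assert (rel, d) == (Relation.PLUGIN, 1)
        assert w == pytest.approx(1 / 3)
        rel, _, _ = classify_relation(graph, "Algin", "Sodium Alginate", definition_cfg)
        assert rel is Relation.SUBSUME

    def test_mode_swap_touches_only_hierarchy_pairs(self, graph, example_cfg, definition_cfg):
        labels = sorted(c.label for c in graph.concepts)
        for a in labels:
            for b in labels:
                r_ex, w_ex, d_ex = classify_relation(graph, a, b, example_cfg)
                r_df, w_df, d_df = classify_relation(graph, a, b, definition_cfg)
                assert (w_ex, d_ex) == (w_df, d_df)
                if r_ex in (Relation.EXACT, Relation.DISSIMILAR):
                    assert r_df is r_ex
                elif graph.is_ancestor(a, b) or graph.is_ancestor(b, a):
                    assert {r_ex, r_df} == {Relation.PLUGIN, Relation.SUBSUME}
                else:  # siblings: Subsume in both modes
                    assert r_df is r_ex is Relation.SUBSUME

    def test_degree_ordering(self):
        assert Relation.DISSIMILAR < Relation.SUBSUME < Relation.PLUGIN < Relation.EXACT


class TestPairTerm:
    @pytest.mark.parametrize(
        "relation,weight,distance,expected,tol",
        [
            (Relation.PLUGIN, 1 / 3, 1, 0.250, 0.001),
            (Relation.SUBSUME, 1 / 3, 1, 0.1665, 0.001),
            (Relation.SUBSUME, 1 / 9, 2, 0.0278, 0.001),
            (Relation.EXACT, 1.0, 1, 1.0, 0),
            (Relation.DISSIMILAR, 0.0, None, 0.0, 0),
        ],
    )
    def test_values(self, relation, weight, distance, expected, tol):
        assert pair_term(relation, weight, distance) == pytest.approx(expected, abs=tol or 1e-12)


class TestGreedyMatch:
    def test_exact_preferred_over_plugin(self):
        """A consumer concept with both a subclass match and a synonym match
        takes the synonym (Exact) partner; the runner-up pairs later."""
        g = graph_from_dict(
            {
                "concepts": ["A", "A-child", "A-syn", "B", "B-child", "C", "C-syn"],
                "subclass": [["A", "A-child"], ["B", "B-child"]],
                "synonyms": [["A", "A-syn"], ["C", "C-syn"]],
            }
        )
        pairs = greedy_match(g, ["A", "B", "C"], ["B-child", "A-syn", "C-syn"])
        got = {(str(p.c_concept), str(p.p_concept), p.relation) for p in pairs}
        assert got == {
            ("A", "A-syn", Relation.EXACT),
            ("B", "B-child", Relation.PLUGIN),
            ("C", "C-syn", Relation.EXACT),
        }

    def test_worked_product1_pairing(self, graph, example_cfg):
        pairs = greedy_match(
            graph,
            ["D-Isoascorbic Acid", "Algin", "Vitamin B3"],
            ["Sodium Alginate", "Ascorbic Acid", "Folic Acid"],
            example_cfg,
        )
        rel = {(str(p.c_concept), str(p.p_concept)): p.relation for p in pairs}
        assert rel[("D-Isoascorbic Acid", "Ascorbic Acid")] is Relation.SUBSUME
        assert rel[("Algin", "Sodium Alginate")] is Relation.PLUGIN
        assert rel[("Vitamin B3", "Folic Acid")] is Relation.DISSIMILAR

    def test_empty_consumer_pads_dissimilar(self, graph):
        pairs = greedy_match(graph, [], ["Algin", "Niacin"])
        assert len(pairs) == 2
        assert all(p.relation is Relation.DISSIMILAR and p.c_concept is None for p in pairs)

    def test_each_concept_used_at_most_once(self, graph):
        pairs = greedy_match(
            graph,
            ["Vitamin C", "E300", "Niacin"],
            ["Ascorbic Acid", "L-Ascorbic Acid"],
        )
        c_used = [p.c_concept.id for p in pairs if p.c_concept]
        p_used = [p.p_concept.id for p in pairs if p.p_concept]
        assert len(c_used) == len(set(c_used))
        assert len(p_used) == len(set(p_used))
        assert len(pairs) == 3  # max(|C|, |P|)


class TestAggregation:
    def test_jaro_worked_value(self):
        assert jaro(1.25, 3, 3) == pytest.approx(0.4167, abs=1e-4)

    def test_jaro_bounds(self):
        assert jaro(0, 3, 3) == 0
        assert jaro(3, 3, 3) == 1

    def test_jaro_symmetric_collapse(self):
        for n in (1, 4, 7):
            m = 0.5 * n
            assert jaro(m, n, n) == pytest.approx(m / n)

    def test_jaro_empty_list_undefined(self):
        with pytest.raises(ValueError):
            jaro(1.0, 0, 3)

    @pytest.mark.parametrize(
        "d_j,l,expected",
        [(0.4167, 2, 0.53336), (0.75, 3, 0.825), (1.0, 5, 1.0)],
    )
    def test_winkler_values(self, d_j, l, expected):
        assert winkler(d_j, l, 0.1) == pytest.approx(expected, abs=1e-5)

    def test_winkler_clamps_at_one(self):
        assert winkler(0.9, 20, 0.1) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(
        m=st.floats(0, 8),
        n_c=st.integers(1, 8),
        n_p=st.integers(1, 8),
        l=st.integers(0, 8),
        k=st.floats(0, 0.12),
    )
    def test_winkler_dominates_jaro_within_unit_interval(self, m, n_c, n_p, l, k):
        m = min(m, (n_c + n_p) / 2)  # degrees cannot exceed the mean size
        d_j = jaro(m, n_c, n_p)
        d_w = winkler(min(d_j, 1.0), l, k)
        assert 0 <= min(d_j, 1.0) <= d_w <= 1


class TestScoreAndPercentage:
    def test_all_dissimilar_scores_zero(self, graph):
        result = evaluate(graph, ["Vitamin B3"], ["Folic Acid"])
        assert result.score == 0
        assert result.percentage == 0

    @pytest.mark.parametrize("score,n,expected", [(1.015625, 3, 33), (1.70034, 3, 56), (0, 5, 0)])
    def test_percentage_floors(self, score, n, expected):
        assert percentage(score, n) == expected

    def test_percentage_clamped(self):
        assert percentage(12.0, 3) == 100
        assert percentage(-1.0, 3) == 0


class TestEvaluate:
    def test_worked_product2_summary(self, worked, example_cfg):
        graph, consumer, _, p2 = worked
        r = evaluate(graph, consumer, p2, example_cfg)
        assert r.m == pytest.approx(2.25)
        assert r.l == 3
        assert r.d_j == pytest.approx(0.75)
        assert r.d_w == pytest.approx(0.825)

    def test_disjoint_product_scores_zero(self, graph):
        r = evaluate(graph, ["Vitamin C"], ["Folic Acid"])
        assert r.score == 0 and r.percentage == 0
        assert all(p.relation is Relation.DISSIMILAR for p in r.pairs)

    def test_all_exact_product_scores_full(self, graph):
        """Identical lists: m = n, d_j = d_w = 1, score = n, percentage 100."""
        terms = ["Algin", "Vitamin B3", "Folic Acid"]
        r = evaluate(graph, terms, terms)
        assert r.m == len(terms)
        assert r.d_j == 1 and r.d_w == 1
        assert r.score == pytest.approx(len(terms))
        assert r.percentage == 100

    def test_unresolvable_ingredient_warns_and_is_reported(self, worked):
        graph, consumer, p1, _ = worked
        from semfood.enhancement import Product

        odd = Product(ean="0", ingredients=p1.ingredients + ["unobtainium"])
        with pytest.warns(UserWarning, match="unobtainium"):
            r = evaluate(graph, consumer, odd)
        assert r.unresolved_ingredients == ["unobtainium"]

    def test_enhancement_inside_evaluate(self, graph):
        cfg = MatchConfig(enhance_relations=frozenset({"synonym"}))
        r = evaluate(graph, ["Niacin"], ["Vitamin B3"], cfg)
        assert r.n_c == 3  # Niacin + Vitamin B3 + Niacinamide
        assert any(p.relation is Relation.EXACT for p in r.pairs)
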