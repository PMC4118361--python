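import pytest

from ccmatch import (
    ContextGraph,
    GraphPattern,
    INCOMPATIBLE,
    brute_force_matches,
    enumerate_maximal_matches,
    initial_matches,
    merge,
    parse_pattern,
    score_kf,
)
from ccmatch.matcher import BRUTE_FORCE_NODE_GUARD

from conftest import random_graph, random_pattern


def keys(matches):
    return {m.key for m in matches}


class TestScoreKf:
    def test_complete_match_scores_one(self):
        p = parse_pattern("A-r->B-s->C")
        g = ContextGraph()
        g.add_edge("A", "B", "r")
        g.add_edge("B", "C", "s")
        (m,) = enumerate_maximal_matches(p, g, 0.1)
        assert m.is_complete and score_kf(m) == 1.0

    def test_uniform_characteristics_give_edge_ratio(self):
        p = parse_pattern("A(-1->B)(-2->C)(-3->D)-4->E")
        g = ContextGraph()
        for lab, n in (("1", "B"), ("2", "C"), ("3", "D")):
            g.add_edge("A", n, lab)
        (m,) = enumerate_maximal_matches(p, g, 0.1)
        assert score_kf(m) == pytest.approx(0.75)

    def test_weighted_boundary_example(self):
        # characteristics (0.9, 0.5, 0.1); solved mass 1.4 of 1.5
        p = GraphPattern("w")
        p.add_edge("A", "B", "r", characteristic=0.9)
        p.add_edge("B", "C", "s", characteristic=0.5)
        p.add_edge("C", "D", "t", characteristic=0.1)
        g = ContextGraph()
        g.add_edge("A", "B", "r")
        g.add_edge("B", "C", "s")
        (m,) = enumerate_maximal_matches(p, g, 0.1)
        assert score_kf(m) == pytest.approx(1.4 / 1.5, abs=1e-12)

    def test_zero_edge_pattern_rejected(self):
        from ccmatch.matcher import Match
        p = GraphPattern("empty")
        with pytest.raises(ValueError):
            score_kf(Match(p, {}, {}))


class TestInitialMatches:
    def test_exact_edge_gives_one_match(self):
        p = parse_pattern("A-r->B")
        g = ContextGraph()
        e = g.add_edge("A", "B", "r")
        assert len(initial_matches(p, e)) == 1

    def test_generic_endpoint_matches_any_node(self):
        p = parse_pattern("?^1-r->B")
        g = ContextGraph()
        ex = g.add_edge("X", "B", "r")
        ey = g.add_edge("Y", "B", "r")
        assert len(initial_matches(p, ex)) == 1
        assert len(initial_matches(p, ey)) == 1

    def test_label_mismatch_gives_nothing(self):
        p = parse_pattern("A-r->B")
        g = ContextGraph()
        e = g.add_edge("A", "B", "s")
        assert initial_matches(p, e) == []

    def test_generic_edge_label_matches_anything(self):
        p = parse_pattern("A-?->B")
        g = ContextGraph()
        e = g.add_edge("A", "B", "whatever")
        assert len(initial_matches(p, e)) == 1


class TestMerge:
    def _singles(self, pattern_text, graph_edges):
        p = parse_pattern(pattern_text)
        g = ContextGraph()
        singles = []
        for f, t, lab in graph_edges:
            e = g.add_edge(f, t, lab)
            singles.extend(initial_matches(p, e))
        return p, singles

    def test_merge_through_shared_node(self):
        _, (m1, m2) = self._singles("A-r->B-s->C",
                                    [("A", "B", "r"), ("B", "C", "s")])
        m = merge(m1, m2)
        assert m is not INCOMPATIBLE and len(m.edge_map) == 2

    def test_conflicting_node_images_incompatible(self):
        p = parse_pattern("?^1(-r->B)-s->C")
        g = ContextGraph()
        e1 = g.add_edge("X", "B", "r")
        e2 = g.add_edge("Y", "C", "s")
        (m1,) = initial_matches(p, e1)
        (m2,) = initial_matches(p, e2)
        assert merge(m1, m2) is INCOMPATIBLE  # ?^1 -> X vs ?^1 -> Y

    def test_injectivity_two_generics_one_node(self):
        p = GraphPattern("inj")
        a, b = p.generic(1), p.generic(2)
        p.add_edge(a, "B", "r")
        p.add_edge(b, "B", "s")
        g = ContextGraph()
        e1 = g.add_edge("X", "B", "r")
        e2 = g.add_edge("X", "B", "s")
        (m1,) = initial_matches(p, e1)
        (m2,) = initial_matches(p, e2)
        assert merge(m1, m2) is INCOMPATIBLE  # both map to X

    def test_merge_never_decreases_quality(self, rng):
        for _ in range(200):
            g = random_graph(rng, rng.randint(2, 8), rng.randint(1, 12))
            p = random_pattern(rng, rng.randint(2, 5), rng.randint(0, 2))
            if p is None:
                continue
            singles = [s for e in g.edges for s in initial_matches(p, e)]
            for i, m1 in enumerate(singles):
                for m2 in singles[i + 1:]:
                    m = merge(m1, m2)
                    if m is not INCOMPATIBLE:
                        assert score_kf(m) >= max(score_kf(m1), score_kf(m2))


class TestEnumerate:
    def test_partial_match_shows_missing_associations(self, shopping_pattern):
        g = ContextGraph()
        g.add_edge("Emily", "Hall", "is-in")
        g.add_edge("Emily", "keys", "has")
        p = shopping_pattern
        matches = enumerate_maximal_matches(p, g, 0.1)
        assert len(matches) == 1
        (m,) = matches
        missing = {e.to.label for e in m.unsolved_edges}
        assert missing == {"wallet", "shopping bag", "city clothes"}

    def test_identical_graph_gives_single_complete_match(self):
        p = parse_pattern("A(-r->B)-s->C")
        g = ContextGraph()
        g.add_edge("A", "B", "r")
        g.add_edge("A", "C", "s")
        matches = enumerate_maximal_matches(p, g, 0.5)
        assert len(matches) == 1 and next(iter(matches)).is_complete

    def test_two_milk_crates_give_both_orderings(self):
        p = GraphPattern("2milk")
        c1, c2 = p.generic(1), p.generic(2)
        p.add_edge("Fridge", c1, "contains")
        p.add_edge(c1, "Milk", "is")
        p.add_edge("Fridge", c2, "contains")
        p.add_edge(c2, "Milk", "is")
        g = ContextGraph()
        for crate in ("crate1", "crate2"):
            g.add_edge("Fridge", crate, "contains")
            g.add_edge(crate, "Milk", "is")
        bf = brute_force_matches(p, g)
        complete = [m for m in bf if m.is_complete]
        assert len(complete) == 2  # injective: ?^1 != ?^2, both orderings
        assert keys(enumerate_maximal_matches(p, g, 0.1)) == keys(bf)

    def test_disjoint_labels_give_empty_result(self):
        p = parse_pattern("A-r->B")
        g = ContextGraph()
        g.add_edge("X", "Y", "z")
        assert enumerate_maximal_matches(p, g, 0.1) == set()
        assert brute_force_matches(p, g) == set()

    def test_brute_force_guard(self):
        g = ContextGraph()
        for i in range(BRUTE_FORCE_NODE_GUARD + 2):
            g.add_edge(f"N{i}", f"N{i + 1}", "r")
        with pytest.raises(ValueError):
            brute_force_matches(parse_pattern("A-r->B"), g)

    def test_min_kf_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_maximal_matches(parse_pattern("A-r->B"),
                                      ContextGraph(), 0.0)


class TestNetworkxCrossCheck:
    def test_complete_match_count_agrees_with_networkx(self, rng):
        """Complete matches are exactly networkx's label-respecting
        subgraph monomorphisms (instances without parallel edges)."""
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.isomorphism import DiGraphMatcher

        checked = 0
        while checked < 100:
            g = ContextGraph()
            for _ in range(rng.randint(1, 12)):
                f, t = f"N{rng.randint(0, 5)}", f"N{rng.randint(0, 5)}"
                lab = rng.choice(["r", "s"])
                if f != t and g.get_edge(f, t) is None \
                        and g.get_edge(f, t, "r") is None \
                        and g.get_edge(f, t, "s") is None:
                    g.add_edge(f, t, lab)
            p = random_pattern(rng, rng.randint(1, 4), rng.randint(0, 2))
            if p is None or any(e.is_generic_label for e in p.edges):
                continue
            seen_pairs = set()
            ok = True
            for e in p.edges:
                if (e.frm, e.to) in seen_pairs:
                    ok = False  # keep instances free of parallel edges
                seen_pairs.add((e.frm, e.to))
            if not ok:
                continue
            checked += 1

            ours = sum(m.is_complete
                       for m in enumerate_maximal_matches(p, g, 1e-9))

            G = nx.DiGraph()
            for node in g.nodes:
                G.add_node(node, label=node)
            for e in g.edges:
                G.add_edge(e.frm, e.to, label=e.label)
            P = nx.DiGraph()
            for node in p.nodes:
                P.add_node(str(node), generic=node.is_generic,
                           label=node.label)
            for e in p.edges:
                P.add_edge(str(e.frm), str(e.to), label=e.label)

            gm = DiGraphMatcher(
                G, P,
                node_match=lambda gn, pn: pn["generic"]
                or gn["label"] == pn["label"],
                edge_match=lambda ge, pe: ge["label"] == pe["label"])
            theirs = sum(1 for _ in gm.subgraph_monomorphisms_iter())
            assert ours == theirs


class TestOracleEquivalence:
    def test_growth_equals_brute_force_on_random_instances(self, rng):
        checked = 0
        while checked < 300:
            g = random_graph(rng, rng.randint(2, 10), rng.randint(1, 14))
            p = random_pattern(rng, rng.randint(1, 5), rng.randint(0, 2))
            if p is None:
                continue
            checked += 1
            grown = enumerate_maximal_matches(p, g, 1e-9)
            assert keys(grown) == keys(brute_force_matches(p, g))
            for m in grown:
                self._check_match_invariants(m)

    @staticmethod
    def _check_match_invariants(m):
        # f_v injective
        assert len(set(m.node_map.values())) == len(m.node_map)
        # minimality: every mapped node is an endpoint of a solved edge
        pedges = m.pattern.edges
        touched = set()
        for i in m.edge_map:
            touched.update((pedges[i].frm, pedges[i].to))
        assert set(m.node_map) == touched
        # k within bounds, complete iff nothing unsolved
        assert 0 <= m.k <= len(pedges) - 1
        assert (m.k == 0) == (not m.unsolved_edges)
        # solved edges map to compatible graph edges
        for i, (f, t, lab) in m.edge_map.items():
            pe = pedges[i]
            assert pe.is_generic_label or pe.label == lab
            assert m.node_map[pe.frm] == f and m.node_map[pe.to] == t
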