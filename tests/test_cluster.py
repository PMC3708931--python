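"""Vertex weighting, complex prediction, cohesive growth, subcluster removal."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_weighted, random_mi_graph, vertex_weight_oracle

from coexmod.cluster import (
    DetectionParams,
    Module,
    ModuleSet,
    cohesiveness,
    detect_kcore_complexes,
    grow_cohesive_modules,
    merge_most_similar,
    module_stats,
    overlap_score,
    postprocess_complexes,
    predict_complexes,
    remove_subclusters,
    vertex_weights,
)
from coexmod.network import MI_KEY


def unit_clique(labels):
    g = nx.Graph()
    for u, v in itertools.combinations(labels, 2):
        g.add_edge(u, v, **{MI_KEY: 1.0})
    return g


class TestVertexWeights:
    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("solo")
        assert vertex_weights(g)["solo"] == 0.0

    def test_k5_node_weight_four(self):
        g = unit_clique("abcde")
        assert all(w == pytest.approx(4.0) for w in vertex_weights(g).values())

    def test_star_center_weight(self):
        # K1,4 center: highest core of the closed neighborhood is the
        # 1-core (the whole star), density 2*4/(5*4) = 0.4
        g = unit_clique("ab").copy()
        g = nx.Graph()
        for leaf in "bcde":
            g.add_edge("a", leaf, **{MI_KEY: 1.0})
        w = vertex_weights(g)
        assert w["a"] == pytest.approx(0.4)
        assert w["b"] == pytest.approx(1.0)  # leaf neighborhood is a K2

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = random_mi_graph(rng, int(rng.integers(5, 30)), 0.25)
            w = vertex_weights(g)
            for v in g.nodes:
                assert w[v] == pytest.approx(vertex_weight_oracle(g, v)), v


class TestPredictComplexes:
    def test_single_clique_single_complex(self):
        g = unit_clique("abcdef")
        modules = predict_complexes(g, vertex_weights(g), DetectionParams())
        assert len(modules) == 1
        assert modules.modules[0].members == frozenset("abcdef")

    def test_two_cliques_bridge_vertex_separated(self, two_cliques_with_bridge_vertex):
        g = two_cliques_with_bridge_vertex
        modules = predict_complexes(g, vertex_weights(g), DetectionParams(vwp=0.2))
        sets = [m.members for m in modules]
        assert frozenset(f"a{i}" for i in range(5)) in sets
        assert frozenset(f"b{i}" for i in range(5)) in sets
        # the low-weight bridge vertex joins neither clique complex
        assert frozenset(["bridge"]) in sets

    def test_vwp_zero_uniform_cycle_one_complex_per_component(self):
        g = nx.Graph()
        for comp, labels in enumerate(("abcd", "wxyz")):
            cyc = list(labels)
            for i, u in enumerate(cyc):
                g.add_edge(u, cyc[(i + 1) % len(cyc)], **{MI_KEY: 1.0})
        modules = predict_complexes(g, vertex_weights(g), DetectionParams(vwp=0.0))
        assert sorted((m.members for m in modules), key=sorted) == [
            frozenset("abcd"),
            frozenset("wxyz"),
        ]

    def test_growth_never_overlaps(self):
        rng = np.random.default_rng(23)
        g = random_mi_graph(rng, 25, 0.2)
        modules = predict_complexes(g, vertex_weights(g), DetectionParams())
        seen = set()
        for m in modules:
            assert not (m.members & seen)
            seen |= m.members


class TestPostprocess:
    def test_two_node_complex_removed(self):
        g = unit_clique("ab")
        modules = ModuleSet([Module("C1", frozenset("ab"), 1.0, "kcore_complex")])
        assert len(postprocess_complexes(g, modules, DetectionParams())) == 0

    def test_triangle_kept(self):
        g = unit_clique("abc")
        modules = ModuleSet([Module("C1", frozenset("abc"), 1.0, "kcore_complex")])
        assert len(postprocess_complexes(g, modules, DetectionParams())) == 1

    def test_fluff_adds_overlapping_neighbor(self):
        # outside node adjacent to 2 of 3 triangle members: density 2/3 > 0.5
        g = unit_clique("abc")
        g.add_edge("x", "a", **{MI_KEY: 1.0})
        g.add_edge("x", "b", **{MI_KEY: 1.0})
        modules = ModuleSet([Module("C1", frozenset("abc"), 1.0, "kcore_complex")])
        out = postprocess_complexes(
            g, modules, DetectionParams(fluff=True, fluff_threshold=0.5)
        )
        assert out.modules[0].members == frozenset("abcx")

    def test_haircut_trims_pendants(self):
        g = unit_clique("abc")
        g.add_edge("p", "a", **{MI_KEY: 1.0})
        modules = ModuleSet([Module("C1", frozenset("abcp"), 1.0, "kcore_complex")])
        out = postprocess_complexes(g, modules, DetectionParams(haircut=True))
        assert out.modules[0].members == frozenset("abc")


class TestCohesiveGrowth:
    def test_isolated_k4_cohesiveness_one(self):
        g = unit_clique("abcd")
        modules = grow_cohesive_modules(g, DetectionParams())
        assert len(modules) == 1
        assert modules.modules[0].members == frozenset("abcd")
        assert modules.modules[0].score == pytest.approx(1.0)

    def test_pendant_absorbed_at_local_maximum(self):
        # f(K4) = 6/(6+1); adding the pendant gives 7/7 = 1
        g = unit_clique("abcd")
        g.add_edge("d", "p", **{MI_KEY: 1.0})
        modules = grow_cohesive_modules(g, DetectionParams())
        assert modules.modules[0].members == frozenset("abcdp")
        assert cohesiveness(g, "abcd") == pytest.approx(6 / 7)

    def test_overlap_score_arithmetic(self):
        assert overlap_score("abcd", "cdef") == pytest.approx(0.25)

    def test_low_overlap_modules_not_merged(self):
        g = unit_clique("abcd")
        h = unit_clique("cdef")
        g.add_edges_from(h.edges(data=True))
        modules = grow_cohesive_modules(g, DetectionParams(overlap_merge_threshold=0.8))
        assert all(len(m.members) < 7 for m in modules)

    def test_local_maximum_certificate(self):
        # removing any single member must not increase cohesiveness
        rng = np.random.default_rng(31)
        g = random_mi_graph(rng, 20, 0.25)
        modules = grow_cohesive_modules(g, DetectionParams(min_module_size=1))
        for m in modules:
            f = cohesiveness(g, m.members)
            for v in m.members:
                if len(m.members) > 1:
                    assert cohesiveness(g, m.members - {v}) <= f + 1e-9

    def test_min_size_filter(self):
        g = unit_clique("ab")
        assert len(grow_cohesive_modules(g, DetectionParams(min_module_size=3))) == 0

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(37)
        g = random_mi_graph(rng, 30, 0.15)
        a = grow_cohesive_modules(g, DetectionParams())
        b = grow_cohesive_modules(g, DetectionParams())
        assert [m.members for m in a] == [m.members for m in b]
        assert [m.score for m in a] == [m.score for m in b]


class TestSubclusterRemoval:
    def _mods(self, *sets):
        return ModuleSet(
            [Module(f"M{i}", frozenset(s), 1.0, "cohesive") for i, s in enumerate(sets)]
        )

    def test_strict_subset_removed(self):
        out = remove_subclusters(self._mods("abc", "abcd"), 1.0)
        assert [m.members for m in out] == [frozenset("abcd")]

    def test_disjoint_unchanged(self):
        out = remove_subclusters(self._mods("abc", "xyz"), 1.0)
        assert len(out) == 2

    def test_equal_size_never_removed(self):
        out = remove_subclusters(self._mods("abc", "abc"), 1.0)
        assert len(out) == 2

    def test_partial_containment_threshold(self):
        # 3 of 4 members of A inside B: removed at theta 0.75, kept at 1.0
        mods = self._mods("abcx", "abcdef")
        assert len(remove_subclusters(mods, 0.75)) == 1
        assert len(remove_subclusters(mods, 1.0)) == 2

    def test_no_cascade_single_pass(self):
        # B is contained in C and A in B; all judged against the original set
        mods = self._mods("ab", "abc", "abcd")
        out = remove_subclusters(mods, 1.0)
        assert [m.members for m in out] == [frozenset("abcd")]

    def test_output_free_of_contained_pairs(self):
        rng = np.random.default_rng(41)
        universe = [f"g{i}" for i in range(30)]
        sets = [
            frozenset(rng.choice(universe, size=rng.integers(3, 10), replace=False))
            for _ in range(40)
        ]
        out = remove_subclusters(
            ModuleSet([Module(f"M{i}", s, 1.0, "cohesive") for i, s in enumerate(sets)]),
            1.0,
        )
        for a, b in itertools.permutations(out, 2):
            if len(b) > len(a):
                assert len(a.members & b.members) / len(a) < 1.0


class TestMergeMostSimilar:
    def _mods(self, *sets):
        return ModuleSet(
            [Module(f"M{i}", frozenset(s), 1.0, "cohesive") for i, s in enumerate(sets)]
        )

    def test_largest_intersection_wins(self):
        merged = merge_most_similar(self._mods("abc", "bcd", "xy"))
        assert merged.members == frozenset("abcd")

    def test_all_disjoint_lexicographic_tie(self):
        merged = merge_most_similar(self._mods("ab", "cd", "ef"))
        assert merged.members == frozenset("abcd")  # ids M0 + M1

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(43)
        universe = [f"g{i}" for i in range(20)]
        sets = [
            frozenset(rng.choice(universe, size=8, replace=False)) for _ in range(10)
        ]
        mods = self._mods(*sets)
        merged = merge_most_similar(mods)
        best = max(
            itertools.combinations(mods, 2),
            key=lambda ab: (
                len(ab[0].members & ab[1].members),
                overlap_score(ab[0].members, ab[1].members),
                [-ord(c) for c in ab[0].module_id + ab[1].module_id],
            ),
        )
        assert merged.members == best[0].members | best[1].members

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            merge_most_similar(self._mods("abc"))


class TestModuleStats:
    def _mods(self, *sets):
        return ModuleSet(
            [Module(f"M{i}", frozenset(s), 1.0, "cohesive") for i, s in enumerate(sets)]
        )

    def test_multiplicity_and_unique(self):
        s = module_stats(self._mods("abc", "bcd"))
        assert s["genes_with_multiplicity"] == 6
        assert s["unique_genes"] == 4

    def test_empty_set_zeros(self):
        s = module_stats(ModuleSet([]))
        assert (s["n_modules"], s["genes_with_multiplicity"], s["unique_genes"]) == (0, 0, 0)

    def test_probe_collapse(self):
        s = module_stats(self._mods(["p1", "p2"], ["p2", "p3"]),
                         probe_to_gene={"p1": "gA", "p2": "gA", "p3": "gB"})
        assert s["genes_with_multiplicity"] == 3  # {gA} + {gA, gB}
        assert s["unique_genes"] == 2

    def test_matches_recount(self):
        rng = np.random.default_rng(47)
        universe = [f"g{i}" for i in range(15)]
        sets = [
            frozenset(rng.choice(universe, size=5, replace=False)) for _ in range(8)
        ]
        s = module_stats(self._mods(*sets))
        assert s["genes_with_multiplicity"] == sum(len(x) for x in sets)
        assert s["unique_genes"] == len(frozenset().union(*sets))


class TestKcoreEndToEnd:
    def test_detects_cliques_in_two_component_graph(self):
        g = unit_clique("abcde")
        h = unit_clique("vwxyz")
        g.add_edges_from(h.edges(data=True))
        modules = detect_kcore_complexes(g, DetectionParams())
        assert sorted((m.members for m in modules), key=sorted) == [
            frozenset("abcde"),
            frozenset("vwxyz"),
        ]
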