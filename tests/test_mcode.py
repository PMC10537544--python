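"""MCODE vertex weighting, complex prediction and post-processing against
hand traces and independent pruning oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netmod import (McodeConfig, ModuleResult, detect_modules, find_complexes,
                    gen_planted_modules, postprocess, rank_and_filter,
                    vertex_weights)
from conftest import random_small_graphs
from oracles import oracle_kcore, oracle_mcode_complexes, oracle_vertex_weight


def clique(labels):
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(labels, 2))
    return g


class TestVertexWeights:
    def test_five_clique(self):
        w = vertex_weights(clique("ABCDE"))
        assert all(v == pytest.approx(4.0) for v in w.values())

    def test_star_center_and_leaves(self):
        g = nx.relabel_nodes(nx.star_graph(4), {i: f"N{i}" for i in range(5)})
        w = vertex_weights(g)
        assert w["N0"] == pytest.approx(0.4)  # 1-core of the star, density 4/10
        assert all(w[f"N{i}"] == 0.0 for i in range(1, 5))

    def test_matches_pruning_oracle(self):
        for g in random_small_graphs(max_nodes=9, count=20, seed=77):
            w = vertex_weights(g)
            for v in g.nodes:
                expect = oracle_vertex_weight(list(g.nodes), list(g.edges), v)
                assert w[v] == pytest.approx(expect, abs=1e-12), v


class TestFindComplexes:
    def test_single_five_clique(self):
        g = clique("ABCDE")
        out = find_complexes(g, vertex_weights(g))
        assert len(out) == 1
        assert out[0].members == frozenset("ABCDE")
        assert out[0].score == pytest.approx(5.0)

    def test_bridged_cliques_merge(self):
        # Both bridge endpoints keep the full weight of their dense
        # neighborhood core (the opposite K5 minus the partner), so the greedy
        # expansion crosses the bridge: one 10-node complex, not two.
        g = clique("ABCDE")
        g.add_edges_from(itertools.combinations("FGHIJ", 2))
        g.add_edge("E", "F")
        w = vertex_weights(g)
        assert w["E"] == pytest.approx(4.0) and w["F"] == pytest.approx(4.0)
        out = find_complexes(g, w)
        assert [sorted(c.members) for c in out] == [sorted("ABCDEFGHIJ")]

    def test_matches_reference_trace(self):
        for g in random_small_graphs(max_nodes=9, count=20, seed=55):
            w = vertex_weights(g)
            got = [c.members for c in find_complexes(g, w)]
            assert got == oracle_mcode_complexes(list(g.nodes), list(g.edges), w)

    def test_missing_weights_error(self):
        g = clique("ABC")
        with pytest.raises(ValueError, match="missing"):
            find_complexes(g, {"A": 1.0})


class TestPostprocess:
    def test_haircut_removes_pendant(self):
        g = clique("ABCD")
        g.add_edge("D", "E")
        mod = ModuleResult(members=frozenset("ABCDE"), density=0.0, score=0.0, seed="A")
        out = postprocess([mod], g)
        assert out[0].members == frozenset("ABCD")
        assert out[0].density == pytest.approx(1.0)
        assert out[0].score == pytest.approx(4.0)

    def test_tree_complex_discarded(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        mod = ModuleResult(members=frozenset("ABCD"), density=0.5, score=2.0, seed="A")
        assert postprocess([mod], g) == []

    def test_two_core_module_is_fixed_point(self):
        g = clique("ABCD")
        mod = ModuleResult(members=frozenset("ABCD"), density=1.0, score=4.0, seed="A")
        out = postprocess([mod], g)
        assert out[0].members == frozenset("ABCD")


class TestRankAndFilter:
    def test_score_boundary_strict(self):
        six = ModuleResult(members=frozenset("ABCDEF"), density=1.0, score=6.0, seed="A")
        five = ModuleResult(members=frozenset("GHIJK"), density=1.0, score=5.0, seed="G")
        kept = rank_and_filter([five, six])
        assert [m.members for m in kept] == [six.members]
        assert kept[0].rank == 1


class TestDetectModules:
    def test_planted_benchmark_recovery(self):
        g, truths = gen_planted_modules(300, 0.01, ((8, 1.0, 2), (7, 1.0, 2), (6, 1.0, 2)),
                                        seed=3)
        mods = detect_modules(g)
        assert len(mods) >= 3
        jaccards = []
        for truth in truths:
            best = max(len(truth & m.members) / len(truth | m.members) for m in mods)
            jaccards.append(best)
        assert all(j >= 0.8 for j in jaccards)
        # planted modules rank in size order 8 > 7 > 6
        top3 = sorted(mods, key=lambda m: m.rank)[:3]
        assert [len(m.members) for m in top3] == sorted((len(t) for t in truths), reverse=True)

    def test_module_invariants(self):
        g, _ = gen_planted_modules(200, 0.02, ((6, 1.0, 2), (5, 0.9, 1)), seed=9)
        cfg = McodeConfig(min_module_score=0.0)
        mods = detect_modules(g, cfg)
        seen: set[str] = set()
        for m in mods:
            assert not (m.members & seen)  # node-disjoint with fluff off
            seen |= m.members
            sub = g.subgraph(m.members)
            assert nx.is_connected(sub)
            assert oracle_kcore(list(sub.nodes), list(sub.edges), 2)
            n, e = sub.number_of_nodes(), sub.number_of_edges()
            assert m.score == pytest.approx(2 * e / (n - 1))  # density × n recomputed

    def test_relabeling_invariance(self):
        for g in random_small_graphs(max_nodes=8, count=10, seed=21):
            mapping = {v: f"Z{v}" for v in g.nodes}
            h = nx.relabel_nodes(g, mapping)
            cfg = McodeConfig(min_module_score=0.0)
            mods_g = {frozenset(mapping[v] for v in m.members) for m in detect_modules(g, cfg)}
            mods_h = {m.members for m in detect_modules(h, cfg)}
            assert mods_g == mods_h

    def test_lower_cutoff_never_grows_complexes(self):
        g, _ = gen_planted_modules(150, 0.02, ((6, 1.0, 2),), seed=13)
        w = vertex_weights(g)
        loose = {c.seed: c.members for c in find_complexes(g, w, McodeConfig(node_score_cutoff=0.2))}
        tight = {c.seed: c.members for c in find_complexes(g, w, McodeConfig(node_score_cutoff=0.05))}
        for seed, members in tight.items():
            if seed in loose:
                assert len(members) <= len(loose[seed])
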