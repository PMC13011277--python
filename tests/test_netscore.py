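"""Network scoring: proximity measures, permutation null, PageRank, filters."""

import networkx as nx
import numpy as np
import pytest

from optisyn import netscore
from optisyn.netscore import (PPIDistances, apply_score_filters, closest_distance,
                              hscore, max_module_diameter, overlap_rate,
                              pagerank_prioritize, proximity_z, separation_score)

from conftest import brute_closest, brute_within


class TestOverlapAndHscore:
    def test_overlap_rate_examples(self):
        assert overlap_rate({"t1", "t2"}, {"t1", "t2"}) == 1.0
        assert overlap_rate({"t1", "t2"}, {"t9"}) == 0.0
        many = {f"t{i}" for i in range(200)}
        assert overlap_rate(many, {"t0"}) == pytest.approx(0.005)

    def test_overlap_rate_empty_herb_set(self):
        with pytest.raises(ValueError):
            overlap_rate(set(), {"t1"})

    def test_overlap_alternative_denominators(self):
        assert overlap_rate({"a", "b"}, {"b", "c"}, denominator="union") == pytest.approx(1 / 3)
        assert overlap_rate({"a", "b"}, {"b", "c"}, denominator="disease") == pytest.approx(0.5)

    def test_hscore_hand_examples(self, tiny_network):
        # h1: c1 targets {t1,t3} (one disease gene), c2 targets {t2} (disease)
        # walk mass: (1/2)(1/2 + 1) = 0.75
        assert hscore(tiny_network, "h1") == pytest.approx(0.75)
        # h2: c3 -> t4 only, no disease gene reached
        assert hscore(tiny_network, "h2") == 0.0

    def test_hscore_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            herbs = ["h"]
            compounds = [f"c{i}" for i in range(int(rng.integers(1, 5)))]
            targets = [f"t{i}" for i in range(int(rng.integers(2, 8)))]
            hc = {("h", c) for c in compounds}
            ct = set()
            for c in compounds:
                k = int(rng.integers(1, len(targets) + 1))
                for t in rng.choice(targets, size=k, replace=False):
                    ct.add((c, t))
            disease = set(rng.choice(targets, size=max(1, len(targets) // 3),
                                     replace=False))
            from optisyn.network import HeteroNetwork
            net = HeteroNetwork(
                herbs=frozenset(herbs), compounds=frozenset(compounds),
                targets=frozenset(targets), disease_genes=frozenset(disease),
                herb_compound_edges=frozenset(hc),
                compound_target_edges=frozenset(ct), ppi_edges=frozenset())
            # oracle: enumerate herb->compound->target paths with walk weights
            expected = 0.0
            for c in compounds:
                tgts = [t for (cc, t) in ct if cc == c]
                for t in tgts:
                    if t in disease:
                        expected += (1 / len(compounds)) * (1 / len(tgts))
            assert hscore(net, "h") == pytest.approx(expected, abs=1e-12)

    def test_hscore_requires_compounds(self, tiny_network):
        with pytest.raises(ValueError):
            hscore(tiny_network, "h_unknown")


class TestDistances:
    def test_path_graph_examples(self, path_graph):
        assert closest_distance(path_graph, {"t1"}, {"t4"}) == 3.0
        assert closest_distance(path_graph, {"t1", "t2"}, {"t1", "t2"}) == 0.0
        # brute force over all pairs: (2+1+1+2)/4
        assert closest_distance(path_graph, {"t1", "t2"}, {"t3", "t4"}) == 1.5

    def test_separation_examples(self, path_graph):
        assert separation_score(path_graph, {"t1", "t2"}, {"t3", "t4"}) == pytest.approx(0.5)
        # identical sets overlap topologically
        assert separation_score(path_graph, {"t1", "t2"}, {"t1", "t2"}) <= 0

    def test_separation_rejects_singletons(self, path_graph):
        with pytest.raises(ValueError, match="A"):
            separation_score(path_graph, {"t1"}, {"t3", "t4"})

    def test_disconnected_cliques_with_penalty_separate(self):
        g = nx.union(nx.relabel_nodes(nx.complete_graph(3), lambda i: f"a{i}"),
                     nx.relabel_nodes(nx.complete_graph(3), lambda i: f"b{i}"))
        A = {"a0", "a1", "a2"}
        B = {"b0", "b1", "b2"}
        s = separation_score(g, A, B, penalty=5)
        assert s > 0
        # oracle with the same penalty substitution
        d_ab = brute_closest(g, A, B, 5)
        expected = d_ab - (brute_within(g, A, 5) + brute_within(g, B, 5)) / 2
        assert s == pytest.approx(expected)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for rep in range(200):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.3)),
                                    seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
            nodes = sorted(g.nodes())
            A = set(rng.choice(nodes, size=int(rng.integers(2, max(3, n // 3))),
                               replace=False))
            B = set(rng.choice(nodes, size=int(rng.integers(2, max(3, n // 3))),
                               replace=False))
            dist = PPIDistances(g)
            pen = dist.diameter + 1
            d = closest_distance(dist, A, B)
            assert d == pytest.approx(brute_closest(g, A, B, pen), abs=1e-12)
            s = separation_score(dist, A, B)
            expected = (brute_closest(g, A, B, pen)
                        - (brute_within(g, A, pen) + brute_within(g, B, pen)) / 2)
            assert s == pytest.approx(expected, abs=1e-12)
            assert closest_distance(dist, B, A) == pytest.approx(d, abs=1e-12)

    def test_max_module_diameter(self, path_graph):
        assert max_module_diameter(path_graph, {"t1", "t2", "t3", "t4"}) == 3
        assert max_module_diameter(path_graph, {"t1"}) == 0
        # two disconnected adjacent pairs -> max over components = 1
        assert max_module_diameter(path_graph, {"t1", "t2", "t4"}) == 1


class TestProximityZ:
    def test_rejects_small_n_perm(self, path_graph):
        with pytest.raises(ValueError):
            proximity_z(path_graph, {"t1"}, {"t4"}, n_perm=10, seed=0)

    def test_null_distribution_consistency(self):
        g = nx.barabasi_albert_graph(120, 3, seed=0)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes()})
        dist = PPIDistances(g)
        z, d, null = proximity_z(dist, [f"t{i}" for i in range(5)],
                                 [f"t{i}" for i in range(50, 58)],
                                 n_perm=200, seed=3)
        assert null.n_perm == 200
        assert null.mu == pytest.approx(np.mean(null.samples), abs=1e-12)
        assert z == pytest.approx((d - null.mu) / null.sigma, abs=1e-12)

    def test_seed_reproducibility(self):
        g = nx.barabasi_albert_graph(100, 3, seed=1)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes()})
        dist = PPIDistances(g)
        args = (dist, [f"t{i}" for i in range(6)], [f"t{i}" for i in range(40, 46)])
        z1, _, _ = proximity_z(*args, n_perm=150, seed=42)
        z2, _, _ = proximity_z(*args, n_perm=150, seed=42)
        assert z1 == z2

    def test_null_draw_lands_within_three_sigma(self):
        """A set drawn by the null procedure itself is typical of the null."""
        g = nx.barabasi_albert_graph(150, 3, seed=5)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes()})
        dist = PPIDistances(g)
        rng = np.random.default_rng(0)
        nodes = dist.nodes
        inside = 0
        trials = 60
        for r in range(trials):
            A = [nodes[i] for i in rng.choice(len(nodes), 8, replace=False)]
            B = [nodes[i] for i in rng.choice(len(nodes), 8, replace=False)]
            z, _, _ = proximity_z(dist, A, B, n_perm=200, seed=100 + r)
            inside += abs(z) < 3
        assert inside / trials >= 0.95


class TestPageRank:
    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        retained, scores = pagerank_prioritize(g)
        assert scores["a"] == pytest.approx(1.0)
        assert retained == ["a"]

    def test_two_node_symmetry(self):
        g = nx.Graph([("a", "b")])
        _, scores = pagerank_prioritize(g)
        assert scores["a"] == pytest.approx(0.5, abs=1e-9)
        assert scores["b"] == pytest.approx(0.5, abs=1e-9)

    def test_star_graph_closed_form(self):
        g = nx.star_graph(4)
        _, scores = pagerank_prioritize(g, damping=0.85)
        total = sum(scores.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        # closed form for K_{1,4}: center = (1-d)/n + 4d*leaf and
        # leaf = (1-d)/n + d*center/4  =>  center = (1-d)(1+4d) / (n(1-d^2))
        d, n = 0.85, 5
        center = (1 - d) * (1 + 4 * d) / (n * (1 - d**2))
        leaf = (1 - d) / n + d * center / 4
        assert scores[0] == pytest.approx(center, abs=1e-8)
        for i in range(1, 5):
            assert scores[i] == pytest.approx(leaf, abs=1e-8)
            assert scores[0] > scores[i]

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(2**31)))
            _, scores = pagerank_prioritize(g, threshold=0.0)
            ref = nx.pagerank(g, alpha=0.85, tol=1e-12)
            for v in g.nodes():
                assert scores[v] == pytest.approx(ref[v], abs=1e-6)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)


class TestFilters:
    def test_table4_mscore_rule_keeps_all_eight(self, table4):
        res = apply_score_filters(table4, [("mscore", ">", 5)])
        assert len(res.retained) == 8

    def test_impossible_bound_empties(self, table4):
        res = apply_score_filters(table4, [("overlap_rate", ">", 1)])
        assert res.retained == []

    def test_hscore_strict_vs_inclusive_boundary(self, table4):
        strict = apply_score_filters(table4, [("hscore", ">", 0.001)])
        assert "Achyranthis Bidentatae Radix" not in strict.retained
        assert len(strict.retained) == 7
        inclusive = apply_score_filters(table4, [("hscore", ">=", 0.001)])
        assert "Achyranthis Bidentatae Radix" in inclusive.retained
        assert len(inclusive.retained) == 8

    def test_unknown_column(self, table4):
        with pytest.raises(KeyError):
            apply_score_filters(table4, [("nope", ">", 0)])

    def test_survivor_counts_per_rule(self, table4):
        res = apply_score_filters(table4, [("mscore", ">", 19), ("gcn_degree", ">", 12)])
        assert res.per_rule_survivors["mscore > 19"] == 5
        assert res.per_rule_survivors["gcn_degree > 12"] == 4
        assert set(res.retained) == {"Myrrha", "Lycii Fructus"}
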