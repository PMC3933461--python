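"""Seeded spin-glass module search, modularity, and permutation significance."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_wnet, two_clique_graph, wnet_from_weighted_graph
from expmods._anneal import partition_hamiltonian_csr, potts_anneal
from expmods.hotspot import (
    AnnealSchedule,
    HotspotConfig,
    HotspotModule,
    _component_csr,
    detect_hotspots,
    module_modularity,
    module_weight_density,
    permutation_pvalue,
    select_seeds,
    spinglass_module,
)
from oracles import exact_permutation_pvalue, exhaustive_seed_community


class TestSelectSeeds:
    def test_absolute_ranking_admits_downregulated_genes(self):
        t = pd.Series({"A": 3.0, "B": -5.0, "C": 1.0})
        assert select_seeds(t, ["A", "B", "C"], 2) == ["B", "A"]

    def test_k_larger_than_network_truncates_with_warning(self):
        t = pd.Series({"A": 1.0, "B": 2.0})
        with pytest.warns(UserWarning):
            seeds = select_seeds(t, ["A", "B"], 5)
        assert seeds == ["B", "A"]

    def test_matches_sort_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        t = pd.Series(rng.normal(0, 2, 20), index=genes)
        seeds = select_seeds(t, genes, 7)
        expected = [g for g, _ in sorted(t.items(), key=lambda kv: (-abs(kv[1]), kv[0]))][:7]
        assert seeds == expected

    def test_ties_break_lexicographically(self):
        t = pd.Series({"B": 2.0, "A": -2.0, "C": 1.0})
        assert select_seeds(t, t.index, 2) == ["A", "B"]


def _csr_and_index(wnet, seed):
    nodes, indptr, indices, weights = _component_csr(wnet, seed)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b, w in wnet.graph.subgraph(nodes).edges.data("weight"):
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = w
    return nodes, idx, adj, (indptr, indices, weights)


class TestSpinglassOracleEquivalence:
    @pytest.mark.parametrize("gamma", [0.25, 0.5, 1.0])
    def test_two_clique_graph_matches_exhaustive_partition(self, gamma):
        """The annealed community around the seed equals the community of
        the exhaustively best partition on a 12-node two-clique graph."""
        wnet = wnet_from_weighted_graph(two_clique_graph())
        nodes, idx, adj, _ = _csr_and_index(wnet, "a0")
        oracle, h, amb = exhaustive_seed_community(adj, gamma, idx["a0"])
        assert amb == 0
        oracle_names = {nodes[i] for i in oracle}
        cfg = HotspotConfig(gamma=gamma, min_module_size=1, rng_seed=17)
        mod = spinglass_module(wnet, "a0", cfg)
        assert set(mod.members) == oracle_names

    def test_heavy_clique_is_recovered_at_protocol_resolution(self):
        """At gamma = 0.5 the seed's heavy clique separates from the light one."""
        wnet = wnet_from_weighted_graph(two_clique_graph())
        mod = spinglass_module(wnet, "a0", HotspotConfig(gamma=0.5, min_module_size=1, rng_seed=3))
        assert set(mod.members) == {f"a{i}" for i in range(6)}

    @pytest.mark.parametrize("gamma", [0.5, 1.0])
    def test_random_weighted_graph_matches_exhaustive_partition(self, gamma):
        rng = np.random.default_rng(99)
        import networkx as nx

        g = nx.gnp_random_graph(9, 0.45, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(9)})
        for a, b in g.edges:
            g.edges[a, b]["weight"] = float(rng.uniform(0.05, 1.0))
        wnet = wnet_from_weighted_graph(g)
        seed = "n0"
        nodes, idx, adj, _ = _csr_and_index(wnet, seed)
        oracle, h, amb = exhaustive_seed_community(adj, gamma, idx[seed])
        assert amb == 0
        oracle_names = {nodes[i] for i in oracle}
        mod = spinglass_module(wnet, seed, HotspotConfig(gamma=gamma, min_module_size=1, rng_seed=1))
        assert set(mod.members) == oracle_names

    def test_restart_level_agreement_rate(self):
        """Single annealing restarts find the exhaustive optimum in >=95%
        of runs; the multi-restart consensus always does."""
        wnet = wnet_from_weighted_graph(two_clique_graph())
        nodes, idx, adj, csr = _csr_and_index(wnet, "a0")
        indptr, indices, weights = csr
        oracle, h_opt, _ = exhaustive_seed_community(adj, 0.5, idx["a0"])
        hits = 0
        for r in range(20):
            sigma, h = potts_anneal(indptr, indices, weights, 12, 0.5,
                                    1.0, 0.01, 0.99, 1.0, 1000 + r)
            found = set(np.flatnonzero(sigma == sigma[idx["a0"]]))
            if found == oracle:
                hits += 1
        assert hits >= 19
        for r in range(3):
            cfg = HotspotConfig(gamma=0.5, min_module_size=1, rng_seed=r,
                                anneal=AnnealSchedule(n_restarts=5))
            mod = spinglass_module(wnet, "a0", cfg)
            assert set(mod.members) == {nodes[i] for i in oracle}

    def test_vanishing_gamma_grows_to_whole_component(self):
        wnet = wnet_from_weighted_graph(two_clique_graph())
        cfg = HotspotConfig(gamma=1e-6, min_module_size=1, rng_seed=0)
        mod = spinglass_module(wnet, "a0", cfg)
        assert set(mod.members) == set(wnet.graph.nodes)

    def test_annealer_reports_true_hamiltonian(self):
        wnet = wnet_from_weighted_graph(two_clique_graph())
        nodes, idx, adj, (indptr, indices, weights) = _csr_and_index(wnet, "a0")
        sigma, h = potts_anneal(indptr, indices, weights, 12, 0.5,
                                1.0, 0.01, 0.99, 1.0, 5)
        h_check = partition_hamiltonian_csr(indptr, indices, weights, 0.5, sigma)
        assert h == pytest.approx(h_check, abs=1e-9)


class TestSpinglassEdgeCases:
    def test_isolated_seed_returns_none(self):
        wnet = build_wnet([("a", "b")], {"a": 2.0, "b": 1.0, "x": 3.0})
        assert spinglass_module(wnet, "x", HotspotConfig(min_module_size=1)) is None

    def test_absent_seed_is_an_error(self):
        wnet = build_wnet([("a", "b")], {"a": 2.0, "b": 1.0})
        with pytest.raises(ValueError):
            spinglass_module(wnet, "zz", HotspotConfig())

    def test_community_below_min_size_returns_none(self):
        wnet = wnet_from_weighted_graph(two_clique_graph())
        assert spinglass_module(wnet, "a0", HotspotConfig(gamma=0.5, min_module_size=10)) is None


class TestModularity:
    def test_edgeless_member_set_scores_zero(self):
        wnet = build_wnet([("a", "b")], {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        assert module_modularity(wnet, {"c", "d"}) == 0.0
        assert module_weight_density(wnet, {"c", "d"}) == 0.0

    def test_triangle_hand_sum(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=0.25)
        g.add_edge("a", "c", weight=0.25)
        wnet = wnet_from_weighted_graph(g)
        assert module_modularity(wnet, {"a", "b", "c"}) == pytest.approx(1.0)
        assert module_weight_density(wnet, {"a", "b", "c"}) == pytest.approx(1 / 3)

    def test_additivity_under_edge_addition(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_node("c")
        wnet = wnet_from_weighted_graph(g)
        m0 = module_modularity(wnet, {"a", "b", "c"})
        g.add_edge("b", "c", weight=0.2)
        wnet2 = wnet_from_weighted_graph(g)
        assert module_modularity(wnet2, {"a", "b", "c"}) == pytest.approx(m0 + 0.2)

    def test_relabeling_invariance(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=0.3)
        g.add_edge("b", "c", weight=0.7)
        wnet = wnet_from_weighted_graph(g)
        relabeled = nx.relabel_nodes(g, {"a": "x", "b": "y", "c": "z"})
        wnet2 = wnet_from_weighted_graph(relabeled)
        assert module_modularity(wnet, {"a", "b"}) == pytest.approx(
            module_modularity(wnet2, {"x", "y"})
        )

    def test_members_outside_network_rejected(self):
        wnet = build_wnet([("a", "b")], {"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError):
            module_modularity(wnet, {"a", "zz"})


class TestPermutationPvalue:
    def test_exchangeable_statistics_give_p_one(self):
        wnet = build_wnet(
            [("a", "b"), ("b", "c"), ("c", "d")],
            {"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0},
        )
        p = permutation_pvalue(wnet, {"a", "b"}, n_perm=200, rng_seed=0)
        assert p == 1.0

    def test_matches_exhaustive_permutation_oracle(self):
        """Monte-Carlo p at n_perm = 5000 lands within 0.02 of the exact
        value from all 120 statistic assignments on a 5-node graph."""
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "c")]
        t = {"a": 5.0, "b": 3.0, "c": 1.0, "d": 0.5, "e": 2.0}
        wnet = build_wnet(edges, t)
        nodes = sorted(t)
        idx = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((5, 5))
        for a, b in edges:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
        abs_t = np.array([abs(t[n]) for n in nodes])
        exact = exact_permutation_pvalue(adj, abs_t, [idx["a"], idx["b"], idx["c"]])
        mc = permutation_pvalue(wnet, {"a", "b", "c"}, n_perm=5000, rng_seed=3)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_deterministic_given_seed(self):
        wnet = build_wnet([("a", "b"), ("b", "c")], {"a": 3.0, "b": 1.0, "c": 0.5})
        p1 = permutation_pvalue(wnet, {"a", "b"}, n_perm=500, rng_seed=11)
        p2 = permutation_pvalue(wnet, {"a", "b"}, n_perm=500, rng_seed=11)
        assert p1 == p2

    def test_never_zero(self):
        wnet = build_wnet([("a", "b"), ("b", "c")], {"a": 9.0, "b": 8.0, "c": 0.1})
        p = permutation_pvalue(wnet, {"a", "b"}, n_perm=100, rng_seed=0)
        assert 0.0 < p <= 1.0

    def test_invalid_n_perm_rejected(self):
        wnet = build_wnet([("a", "b")], {"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            permutation_pvalue(wnet, {"a", "b"}, n_perm=0)


@pytest.fixture(scope="module")
def planted_setup():
    import expmods as em

    planted = [f"G{i:04d}" for i in range(1, 11)]
    expr = em.simulate_expression(
        em.SimulationConfig(n_genes=300, planted_genes=planted,
                            effect_size=4.0, rng_seed=8)
    )
    de = em.moderated_t_test(expr)
    net = em.simulate_interactome(
        em.NetworkSimConfig(n_nodes=300, planted_module_size=10,
                            planted_internal_density=0.9, rng_seed=9)
    )
    wnet = em.weight_edges(em.integrate(net, set(expr.genes)), de)
    return wnet, de, set(planted)


class TestDetectHotspots:
    def test_planted_module_found_and_significant(self, planted_setup):
        wnet, de, planted = planted_setup
        cfg = HotspotConfig(n_seeds=5, gamma=2.0, n_perm=400, rng_seed=1)
        res = detect_hotspots(wnet, de, cfg)
        assert res.modules, "planted hotspot not detected"
        top = res.modules[0]
        assert len(set(top.members) & planted) >= 8
        assert top.p_adj <= 0.05
        assert top.seed in top.members

    def test_deterministic_given_seed(self, planted_setup):
        wnet, de, _ = planted_setup
        cfg = HotspotConfig(n_seeds=5, gamma=2.0, n_perm=200, rng_seed=4)
        r1 = detect_hotspots(wnet, de, cfg)
        r2 = detect_hotspots(wnet, de, cfg)
        assert [m.members for m in r1.modules] == [m.members for m in r2.modules]
        assert [m.p_perm for m in r1.modules] == [m.p_perm for m in r2.modules]

    def test_ranked_by_modularity_and_jaccard_reported(self, planted_setup):
        wnet, de, _ = planted_setup
        cfg = HotspotConfig(n_seeds=5, gamma=2.0, n_perm=200, rng_seed=2)
        res = detect_hotspots(wnet, de, cfg)
        mods = [m.modularity for m in res.modules]
        assert mods == sorted(mods, reverse=True)
        assert res.jaccard.shape == (len(res.modules), len(res.modules))
        if len(res.modules):
            assert np.allclose(np.diag(res.jaccard.to_numpy()), 1.0)

    def test_module_invariants(self, planted_setup):
        wnet, de, _ = planted_setup
        cfg = HotspotConfig(n_seeds=5, gamma=2.0, n_perm=200, rng_seed=2)
        res = detect_hotspots(wnet, de, cfg)
        for m in res.tested:
            assert m.seed in m.members
            assert m.size == len(m.members)
            assert m.modularity >= 0
            assert 0 < m.p_perm <= 1
            assert m.p_adj >= m.p_perm


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(gamma=0.0), dict(n_perm=0), dict(n_seeds=0), dict(alpha=0.0)]
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HotspotConfig(**kwargs)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(cooling=1.5)
        with pytest.raises(ValueError):
            AnnealSchedule(start_temp=0.01, stop_temp=1.0)

    def test_module_invariant_enforced(self):
        with pytest.raises(ValueError):
            HotspotModule(seed="a", members=frozenset({"b"}), modularity=0.0,
                          avg_weight_density=0.0, size=1)
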