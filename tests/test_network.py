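import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizonet.abundance import to_relative
from rhizonet.network import (assign_modules, build_network, classify_roles,
                              network_stats, zi_pi)
from rhizonet.sparcc import CorrelationEstimate, SparccParams, estimate
from rhizonet.synthetic import CommunityDesign, simulate

from conftest import make_table


def manual_estimate(ids, rho, pval) -> CorrelationEstimate:
    rho = pd.DataFrame(rho, index=ids, columns=ids)
    pval = pd.DataFrame(pval, index=ids, columns=ids)
    return CorrelationEstimate(rho=rho, pvalue=pval,
                               basis_variance=pd.Series(1.0, index=ids),
                               variation=rho * 0, params=SparccParams())


class TestBuildNetwork:
    def _three_taxa(self, pvals):
        ids = ["a", "b", "c"]
        rho = np.array([[1, .5, -.4], [.5, 1, .3], [-.4, .3, 1]])
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = pvals[0]
        p[0, 2] = p[2, 0] = pvals[1]
        p[1, 2] = p[2, 1] = pvals[2]
        est = manual_estimate(ids, rho, p)
        counts = np.array([[5, 5], [5, 5], [5, 5]])
        rel = to_relative(make_table(counts, taxon_ids=ids))
        return est, rel

    def test_nothing_significant_gives_empty_edge_set(self):
        est, rel = self._three_taxa([1.0, 1.0, 1.0])
        g = build_network(est, rel, drop_isolated=False)
        assert g.number_of_edges() == 0

    def test_edge_rule_applied_pairwise(self):
        est, rel = self._three_taxa([0.001, 0.5, 0.005])
        g = build_network(est, rel, p_cut=0.01)
        assert set(map(frozenset, g.edges)) == {frozenset({"a", "b"}),
                                                frozenset({"b", "c"})}
        assert g.edges["a", "b"]["sign"] == 1
        assert g.nodes["a"]["abundance"] == pytest.approx(1 / 3)

    def test_id_mismatch_lists_difference(self):
        est, rel = self._three_taxa([0.001, 0.5, 0.005])
        rel2 = to_relative(make_table(np.array([[5, 5], [5, 5]]),
                                      taxon_ids=["a", "x"]))
        with pytest.raises(ValueError, match="x"):
            build_network(est, rel2)

    def test_planted_module_fully_connected_end_to_end(self):
        design = CommunityDesign(
            n_taxa=12, n_samples_per_group=200, groups=[("Col-0", "LP")],
            module_spec=[(3, 0.7)], hub_spec=[], biomarker_spec=[],
            depth_mean=20000, depth_dispersion=0.3, seed=17)
        table, _ = simulate(design)
        est = estimate(table, SparccParams(n_iterations=10,
                                           n_bootstraps=200, seed=2))
        g = build_network(est, to_relative(table), p_cut=0.01)
        mod = table.taxon_ids[:3]
        for u, v in itertools.combinations(mod, 2):
            assert g.has_edge(u, v)


class TestNetworkStats:
    def test_two_cliques_modularity_is_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        module_of = assign_modules(g)
        groups = {}
        for node, m in module_of.items():
            groups.setdefault(m, set()).add(node)
        assert sorted(map(sorted, groups.values())) == \
            [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
        stats = network_stats(g, n_random=0)
        assert stats.modularity == pytest.approx(0.5, abs=1e-12)
        # brute-force oracle: no bipartition beats the cliques
        best = max(
            nx.algorithms.community.modularity(
                g, [set(c), set(g.nodes) - set(c)])
            for k in range(1, 10)
            for c in itertools.combinations(range(10), k))
        assert best == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph(self):
        g = nx.complete_graph(6)
        stats = network_stats(g, n_random=0)
        assert stats.modularity == pytest.approx(0.0, abs=1e-9)
        assert stats.clustering_coefficient == pytest.approx(1.0)
        assert stats.average_degree == pytest.approx(5.0)

    def test_ring_has_no_triangles(self):
        stats = network_stats(nx.cycle_graph(12), n_random=0)
        assert stats.clustering_coefficient == 0.0

    def test_relative_modularity_of_modular_graph_positive(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        stats = network_stats(g, n_random=20, seed=0, swaps_per_edge=10)
        assert stats.relative_modularity is not None
        assert stats.relative_modularity > 0

    def test_greedy_beats_trivial_partition(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        stats = network_stats(g, n_random=0)
        assert stats.modularity >= 0.0


class TestZiPi:
    def test_all_links_within_module_pi_zero(self):
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, 0, "module")
        topo = zi_pi(g)
        assert (topo["pi"] == 0).all()

    def test_equal_split_pi_half(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        nx.set_node_attributes(g, {"x": 0, "a": 0, "b": 1}, "module")
        topo = zi_pi(g)
        assert topo.loc["x", "pi"] == pytest.approx(0.5)

    def test_hub_and_spoke_hand_computation(self):
        # 6-node module: hub wired to 5 spokes; within-degrees [5,1,1,1,1,1]
        # mean 5/3, population sd sqrt(20/9); Zi_hub=(5-5/3)/sd=sqrt(5)
        g = nx.star_graph(5)
        nx.set_node_attributes(g, 0, "module")
        topo = zi_pi(g)
        sd = np.sqrt(20 / 9)
        assert topo.loc[0, "zi"] == pytest.approx((5 - 5 / 3) / sd)
        assert topo.loc[0, "zi"] == pytest.approx(np.sqrt(5))
        assert topo.loc[1, "zi"] == pytest.approx((1 - 5 / 3) / sd)
        assert topo.loc[0, "zi"] > topo["zi"].drop(0).max()

    def test_degree_zero_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        nx.set_node_attributes(g, 0, "module")
        with pytest.raises(ValueError, match="degree 0"):
            zi_pi(g)

    def test_two_cliques_all_peripheral(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        assign_modules(g)
        topo = classify_roles(zi_pi(g))
        assert (topo["zi"] == 0).all() and (topo["pi"] == 0).all()
        assert (topo["role"] == "peripheral").all()
        assert not topo["keystone"].any()

    def test_invariant_under_node_relabeling(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.cycle_graph(5))
        g.add_edge(0, 4)
        assign_modules(g)
        topo = zi_pi(g)
        mapping = {n: f"node_{n}" for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        topo_h = zi_pi(h)
        for n in g.nodes:
            assert topo_h.loc[f"node_{n}", "zi"] == \
                pytest.approx(topo.loc[n, "zi"])
            assert topo_h.loc[f"node_{n}", "pi"] == \
                pytest.approx(topo.loc[n, "pi"])


class TestRoles:
    @pytest.mark.parametrize("zi,pi,role,keystone", [
        (3.0, 0.1, "module hub", True),
        (1.0, 0.8, "connector", True),
        (0.0, 0.0, "peripheral", False),
        (3.0, 0.8, "network hub", True),
    ])
    def test_threshold_rule(self, zi, pi, role, keystone):
        topo = pd.DataFrame({"zi": [zi], "pi": [pi]}, index=["n"])
        out = classify_roles(topo)
        assert out.loc["n", "role"] == role
        assert bool(out.loc["n", "keystone"]) is keystone

    def test_strict_boundary_grid(self):
        grid = [(z, p) for z in (2.4, 2.5, 2.6) for p in (0.61, 0.62, 0.63)]
        topo = pd.DataFrame(grid, columns=["zi", "pi"])
        roles = classify_roles(topo, boundary="strict")["role"].tolist()
        assert roles == ["peripheral", "peripheral", "connector",
                         "peripheral", "peripheral", "connector",
                         "module hub", "module hub", "network hub"]

    def test_inclusive_boundary_counts_threshold_points_as_hubs(self):
        topo = pd.DataFrame({"zi": [2.5, 2.4], "pi": [0.62, 0.62]})
        roles = classify_roles(topo, boundary="inclusive")["role"]
        assert roles.tolist() == ["network hub", "connector"]

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-5, 8, allow_nan=False),
           st.floats(0, 1, allow_nan=False))
    def test_partition_exhaustive_and_exclusive(self, zi, pi):
        topo = pd.DataFrame({"zi": [zi], "pi": [pi]})
        role = classify_roles(topo)["role"].iloc[0]
        assert role in ("peripheral", "connector", "module hub",
                        "network hub")
        # the four conditions are mutually exclusive by construction
        matches = [role == r for r in
                   ("peripheral", "connector", "module hub", "network hub")]
        assert sum(matches) == 1
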