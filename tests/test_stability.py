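import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from rhizonet.abundance import to_relative
from rhizonet.stability import (cohesion, global_efficiency,
                                simulate_robustness, vulnerability,
                                weighted_interaction_strength)

from conftest import attributed_graph, make_table


class TestWMIS:
    def test_constant_positive_weights(self):
        g = attributed_graph([("a", "b", 0.4), ("a", "c", 0.4)])
        assert weighted_interaction_strength(g, "a") == pytest.approx(0.4)

    def test_equal_magnitude_cancellation(self):
        g = attributed_graph([("a", "b", 0.5), ("a", "c", -0.5)])
        assert weighted_interaction_strength(g, "a") == pytest.approx(0.0)

    def test_four_node_weighted_mean_hand_case(self):
        # neighbours b,c,d with b=(2,3,4) and rho=(0.5,-0.2,0.8):
        # wMIS = (2·0.5 − 3·0.2 + 4·0.8)/(2+3+4) = 3.6/9
        g = attributed_graph([("a", "b", 0.5), ("a", "c", -0.2),
                              ("a", "d", 0.8)],
                             abundance={"a": 1, "b": 2, "c": 3, "d": 4})
        assert weighted_interaction_strength(g, "a") == \
            pytest.approx(3.6 / 9)

    def test_no_remaining_neighbours_is_zero(self):
        g = attributed_graph([("a", "b", 0.5)])
        assert weighted_interaction_strength(g, "a", {"a"}) == 0.0


class TestRobustness:
    def test_complete_all_positive_no_secondary_extinction(self):
        g = attributed_graph([(i, j, 0.5) for i, j in
                              itertools.combinations(range(10), 2)])
        res = simulate_robustness(g, 0.5, replicates=20, seed=0)
        np.testing.assert_allclose(res.proportions, 0.5)

    def test_two_node_forced_cascade(self):
        g = attributed_graph([("a", "b", 0.9)])
        res = simulate_robustness(g, 0.5, replicates=10, seed=1)
        np.testing.assert_allclose(res.proportions, 0.0)

    def test_star_matches_conditional_expectation_oracle(self):
        # hub + 10 spokes, f=0.5 → 5 removed. Hub removed (prob 5/11):
        # all spokes isolated → 0. Hub kept: 6 survive → 6/11.
        # E = (6/11)·(6/11) = 36/121.
        g = attributed_graph([("h", f"s{i}", 0.5) for i in range(10)])
        res = simulate_robustness(g, 0.5, replicates=200, seed=3)
        expected = 36 / 121
        per_rep_sd = (6 / 11) * np.sqrt((6 / 11) * (5 / 11))
        assert abs(res.mean - expected) < 3 * per_rep_sd / np.sqrt(200)
        assert set(np.round(res.proportions, 10)) <= {0.0,
                                                      round(6 / 11, 10)}

    def test_negative_only_node_dies_under_leq_rule(self):
        g = attributed_graph([("a", "b", -0.5), ("b", "c", 0.9),
                              ("c", "d", 0.9), ("d", "b", 0.9),
                              ("a", "c", -0.1)])
        res = simulate_robustness(g, 0.2, replicates=5, seed=0, rule="leq")
        assert res.proportions.max() <= 3 / 4  # node 'a' can never persist

    def test_monotone_in_removal_fraction(self):
        g = attributed_graph([(i, j, 0.3) for i, j in
                              nx.gnp_random_graph(20, 0.25, seed=2).edges])
        means = [simulate_robustness(g, f, replicates=100, seed=5).mean
                 for f in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))

    def test_targeted_removal_mode(self):
        g = attributed_graph([("h", f"s{i}", 0.5) for i in range(5)])
        res = simulate_robustness(g, replicates=3, targeted_nodes={"h"})
        np.testing.assert_allclose(res.proportions, 0.0)  # spokes cascade
        assert res.targeted

    def test_bad_fraction_rejected(self):
        g = attributed_graph([("a", "b", 0.5)])
        with pytest.raises(ValueError):
            simulate_robustness(g, 1.5)


class TestEfficiency:
    def test_closed_forms(self):
        assert global_efficiency(nx.complete_graph(5)) == pytest.approx(1.0)
        empty = nx.empty_graph(4)
        assert global_efficiency(empty) == 0.0
        assert global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_agrees_with_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(3, 21))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.7)),
                                    seed=int(rng.integers(1 << 30)))
            A = nx.to_numpy_array(g)
            d = shortest_path(A, unweighted=True)
            with np.errstate(divide="ignore"):
                inv = 1.0 / d
            inv[~np.isfinite(inv)] = 0.0
            np.fill_diagonal(inv, 0.0)
            oracle = inv.sum() / (n * (n - 1))
            assert global_efficiency(g) == pytest.approx(oracle, abs=1e-12)


class TestVulnerability:
    def test_complete_graph_fully_redundant(self):
        res = vulnerability(nx.complete_graph(5))
        np.testing.assert_allclose(res.node_vulnerability, 0.0, atol=1e-12)
        assert res.max_vulnerability == pytest.approx(0.0, abs=1e-12)

    def test_path_cut_vertex(self):
        res = vulnerability(nx.path_graph(3))
        assert res.global_efficiency == pytest.approx(5 / 6)
        assert res.node_vulnerability[1] == pytest.approx(1.0)
        assert res.max_vulnerability == pytest.approx(1.0)

    def test_zero_efficiency_rejected(self):
        with pytest.raises(ValueError):
            vulnerability(nx.empty_graph(4))

    def test_leaf_never_beats_cut_vertex_on_small_graphs(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 20:
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.35,
                                    seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            leaves = [v for v, d in g.degree() if d == 1]
            cuts = list(nx.articulation_points(g))
            if not leaves or not cuts:
                continue
            res = vulnerability(g)
            v_leaf = max(res.node_vulnerability[v] for v in leaves)
            v_cut = max(res.node_vulnerability[v] for v in cuts)
            assert v_leaf <= v_cut + 1e-12
            checked += 1

    def test_planted_bridge_hub_beats_rewired_controls(self):
        # hub bridging two dense clusters vs degree-preserving rewirings
        margins = []
        for seed in range(20):
            g = nx.disjoint_union(nx.complete_graph(8),
                                  nx.complete_graph(8))
            hub = 16
            g.add_edges_from((hub, v) for v in (0, 1, 2, 3, 8, 9, 10, 11))
            planted = vulnerability(g).max_vulnerability
            h = g.copy()
            nx.double_edge_swap(h, nswap=4 * h.number_of_edges(),
                                max_tries=10_000, seed=seed)
            if not nx.is_connected(h):
                continue
            margins.append(planted - vulnerability(h).max_vulnerability)
        assert np.mean(margins) > 0


class TestCohesion:
    def test_sign_contract(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 200, size=(12, 15))
        rel = to_relative(make_table(counts))
        res = cohesion(rel, n_null=50, seed=1)
        assert (res.cohesion["positive"] >= 0).all()
        assert (res.cohesion["negative"] <= 0).all()

    def test_three_taxon_dual_route_oracle(self):
        """A plain-loop reimplementation (same null stream) must agree to
        1e-10 with the vectorised implementation."""
        counts = np.array([[50, 80, 20, 60, 30],
                           [55, 85, 25, 62, 33],
                           [40, 10, 70, 20, 80]])
        rel = to_relative(make_table(counts))
        res = cohesion(rel, n_null=40, seed=7)

        X = rel.fractions.to_numpy()
        D, n = X.shape

        def corr_loops(M):
            C = np.zeros((D, D))
            for i in range(D):
                for j in range(D):
                    if i != j:
                        C[i, j] = np.corrcoef(M[i], M[j])[0, 1]
            return C

        obs = corr_loops(X)
        rng = np.random.default_rng(7)
        null = np.zeros((D, D))
        for _ in range(40):
            P = np.empty_like(X)
            for i in range(D):
                P[i] = X[i, rng.permutation(n)]
            null += corr_loops(P)
        corrected = obs - null / 40
        for j, t in enumerate(rel.taxon_ids):
            row = np.delete(corrected[j], j)
            pos = row[row > 0]
            neg = row[row < 0]
            cj_pos = pos.mean() if pos.size else 0.0
            cj_neg = neg.mean() if neg.size else 0.0
            assert res.connectedness_pos[t] == pytest.approx(cj_pos,
                                                             abs=1e-10)
            assert res.connectedness_neg[t] == pytest.approx(cj_neg,
                                                             abs=1e-10)
        for s_idx, s in enumerate(rel.sample_ids):
            exp_pos = sum(X[j, s_idx] * max(res.connectedness_pos.iloc[j], 0)
                          for j in range(D))
            assert res.cohesion.loc[s, "positive"] == pytest.approx(
                exp_pos, abs=1e-10)

    def test_constant_taxon_zeroed_with_diagnostic(self):
        counts = np.array([[5, 5, 5, 5], [1, 9, 2, 8], [9, 1, 8, 2]])
        rel = to_relative(make_table(counts * 10))
        # make taxon 0 constant in relative abundance
        fr = rel.fractions.copy()
        fr.iloc[0] = 0.2
        fr.iloc[1:] = fr.iloc[1:].div(fr.iloc[1:].sum(axis=0), axis=1) * 0.8
        from rhizonet.abundance import RelativeAbundanceTable
        rel2 = RelativeAbundanceTable(fr)
        res = cohesion(rel2, n_null=20, seed=0)
        assert res.diagnostics["constant_taxa"] == ["t0"]
        assert res.connectedness_pos["t0"] == 0.0

    def test_determinism(self):
        rng = np.random.default_rng(5)
        rel = to_relative(make_table(rng.integers(1, 100, size=(6, 10))))
        a = cohesion(rel, n_null=30, seed=9)
        b = cohesion(rel, n_null=30, seed=9)
        assert a.cohesion.equals(b.cohesion)
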