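"""Proportional thresholding and efficiency vs brute-force / networkx oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from fconntraj import graph as gr
from fconntraj.connectome import devectorize_edges, n_edges


def floyd_warshall_oracle(adj):
    """Brute-force all-pairs hop distances."""
    P = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(P):
        for i in range(P):
            for j in range(P):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def ge_oracle(adj):
    d = floyd_warshall_oracle(adj)
    P = adj.shape[0]
    out = np.zeros(P)
    for n in range(P):
        inv = [1.0 / d[n, m] for m in range(P) if m != n and np.isfinite(d[n, m])]
        out[n] = sum(inv) / (P - 1)
    return out


def le_oracle(adj):
    P = adj.shape[0]
    out = np.zeros(P)
    for n in range(P):
        nbrs = np.flatnonzero(adj[n])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[n] = ge_oracle(sub).mean()
    return out


def random_adjacency(P, p_edge, rng):
    adj = (rng.random((P, P)) < p_edge).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T


class TestThreshold:
    def test_full_proportion_complete_graph(self, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        adj = gr.threshold_top_proportion(m, 1.0)
        assert adj.sum() == 6 * 5  # every off-diagonal pair

    def test_study_scale_edge_count(self, rng):
        m = rng.normal(size=(195, 195))
        m = (m + m.T) / 2
        adj = gr.threshold_top_proportion(m, 0.15)
        assert adj.sum() // 2 == 2838  # ceil(0.15 * 18915)

    def test_single_edge_is_argmax(self):
        m = np.array([[0, 0.9, 0.1], [0.9, 0, 0.5], [0.1, 0.5, 0.0]])
        adj = gr.threshold_top_proportion(m, 1 / 3)
        assert adj[0, 1] == 1 and adj.sum() == 2

    def test_tie_break_by_canonical_order(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0)
        adj = gr.threshold_top_proportion(m, 1 / 6)  # keep 1 of 6 equal edges
        assert adj[0, 1] == 1 and adj.sum() == 2

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            gr.threshold_top_proportion(np.zeros((3, 3)), 0.0)


class TestShortestPaths:
    def test_complete_graph_all_ones(self):
        adj = 1 - np.eye(4, dtype=int)
        d = gr.shortest_path_lengths(adj)
        assert (d[~np.eye(4, dtype=bool)] == 1).all()

    def test_path_graph(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        d = gr.shortest_path_lengths(adj)
        assert d[0, 2] == 2 and d[0, 0] == 0

    def test_unreachable_infinite(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        d = gr.shortest_path_lengths(adj)
        assert np.isinf(d[0, 2])

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(100):
            adj = random_adjacency(10, rng.uniform(0.1, 0.6), rng)
            np.testing.assert_array_equal(
                gr.shortest_path_lengths(adj), floyd_warshall_oracle(adj)
            )


class TestEfficiency:
    def test_complete_graph_unit_efficiency(self):
        adj = 1 - np.eye(4, dtype=int)
        np.testing.assert_allclose(gr.global_efficiency(gr.shortest_path_lengths(adj)), 1.0)
        np.testing.assert_allclose(gr.local_efficiency(adj), 1.0)

    def test_path_end_node(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        ge = gr.global_efficiency(gr.shortest_path_lengths(adj))
        assert ge[0] == pytest.approx((1 + 0.5) / 2)

    def test_isolated_node_zero(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        ge = gr.global_efficiency(gr.shortest_path_lengths(adj))
        assert ge[2] == 0.0

    def test_star_center_zero_local_efficiency(self):
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        le = gr.local_efficiency(adj)
        assert le[0] == 0.0

    def test_oracle_equivalence_random_graphs(self, rng):
        for _ in range(25):
            adj = random_adjacency(10, rng.uniform(0.2, 0.7), rng)
            d = gr.shortest_path_lengths(adj)
            np.testing.assert_allclose(gr.global_efficiency(d), ge_oracle(adj))
            np.testing.assert_allclose(gr.local_efficiency(adj), le_oracle(adj))

    def test_networkx_global_efficiency_average(self, rng):
        # networkx reports the graph-average; our per-node values average to it
        for seed in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            adj = nx.to_numpy_array(g).astype(int)
            ours = gr.global_efficiency(gr.shortest_path_lengths(adj)).mean()
            assert ours == pytest.approx(nx.global_efficiency(g))

    def test_permutation_equivariance(self, rng):
        adj = random_adjacency(8, 0.4, rng)
        perm = rng.permutation(8)
        padj = adj[np.ix_(perm, perm)]
        np.testing.assert_allclose(
            gr.global_efficiency(gr.shortest_path_lengths(padj)),
            gr.global_efficiency(gr.shortest_path_lengths(adj))[perm],
        )
        np.testing.assert_allclose(gr.local_efficiency(padj), gr.local_efficiency(adj)[perm])

    def test_edge_addition_never_decreases_ge(self, rng):
        adj = random_adjacency(8, 0.3, rng)
        missing = [(i, j) for i, j in combinations(range(8), 2) if adj[i, j] == 0]
        if not missing:
            pytest.skip("dense draw")
        i, j = missing[0]
        before = gr.global_efficiency(gr.shortest_path_lengths(adj))
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        after = gr.global_efficiency(gr.shortest_path_lengths(adj2))
        assert np.all(after >= before - 1e-12)


class TestSessionEfficiencies:
    def test_shapes_and_bounds(self, rng):
        P = 12
        edges = rng.normal(size=(5, n_edges(P)))
        ge, le = gr.session_efficiencies(edges, P)
        assert ge.shape == le.shape == (5, P)
        assert ((ge >= 0) & (ge <= 1)).all() and ((le >= 0) & (le <= 1)).all()

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gr.session_efficiencies(rng.normal(size=(3, 10)), 12)


class TestEfficiencyTrajectories:
    def test_injected_trend_recovered(self, study_cohort, rng):
        ages = study_cohort["age_weeks"].to_numpy()
        n_nodes = 6
        vals = rng.normal(0.5, 0.02, (len(study_cohort), n_nodes))
        vals[:, 0] += 0.01 * (ages - 25)  # one node with a real age trend
        effects, fits = gr.efficiency_trajectories(vals, study_cohort)
        assert effects.loc[0, "sign"] == "positive"
        assert effects.loc[0, "beta"] == pytest.approx(0.01, abs=0.002)
        assert (effects.loc[1:, "sign"] == "null").all()
        assert fits["positive"] is not None and fits["positive"].converged

    def test_single_node_valid_result(self, study_cohort, rng):
        vals = rng.normal(0.5, 0.05, (len(study_cohort), 1))
        effects, _ = gr.efficiency_trajectories(vals, study_cohort)
        assert len(effects) == 1
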