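"""Graph construction and nodal metrics against exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

import gliomaconn as gc
from gliomaconn.graph_topology import PRIMARY_SPARSITY, SPARSITY_CANDIDATES


# ---------------------------------------------------------------- oracles

def bfs_lengths(adj, source):
    """All-pairs-from-source shortest path lengths by plain BFS."""
    n = len(adj)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u][v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def betweenness_oracle(adj, v):
    """Enumerate ALL simple paths per pair; count shortest ones through v."""
    n = len(adj)
    total = 0.0
    for s, t in itertools.combinations(range(n), 2):
        if v in (s, t):
            continue
        paths = []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                paths.append(path)
                continue
            for w in range(n):
                if adj[u][w] and w not in path:
                    stack.append((w, path + [w]))
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        total += sum(v in p for p in shortest) / len(shortest)
    return total / ((n - 1) * (n - 2) / 2.0)


def closeness_oracle(adj, v):
    """Wasserman-Faust component-scaled closeness."""
    n = len(adj)
    dist = bfs_lengths(adj, v)
    reach = len(dist) - 1
    if reach == 0:
        return 0.0
    total = sum(dist.values())
    return (reach / total) * (reach / (n - 1))


def clustering_oracle(adj, v):
    nbrs = [u for u in range(len(adj)) if adj[v][u]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(adj[a][b] for a, b in itertools.combinations(nbrs, 2))
    return 2.0 * links / (k * (k - 1))


def graph_to_adj(g, n):
    adj = [[0] * n for _ in range(n)]
    for u, v in g.edges():
        adj[u][v] = adj[v][u] = 1
    return adj


# ---------------------------------------------------------------- tests

class TestBuildGraph:
    def test_edge_count_at_primary_sparsity(self, rng):
        n = 401
        w = rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        fg = gc.build_graph(w, 0.15)
        assert fg.n_edges == 12030  # round(0.15 * 401 * 400 / 2)

    def test_top_ranked_pairs_exactly(self):
        w = np.zeros((4, 4))
        ranking = {(0, 1): 5.0, (0, 2): 4.0, (1, 3): 3.0, (0, 3): 2.0, (1, 2): 1.0, (2, 3): 0.5}
        for (i, j), v in ranking.items():
            w[i, j] = w[j, i] = v
        fg = gc.build_graph(w, 0.5)  # K = 3
        assert set(map(tuple, map(sorted, fg.graph.edges()))) == {(0, 1), (0, 2), (1, 3)}

    def test_sparsity_one_is_complete(self, rng):
        w = rng.standard_normal((8, 8))
        w = (w + w.T) / 2
        fg = gc.build_graph(w, 1.0)
        assert fg.n_edges == 28

    def test_zero_edge_request_rejected(self):
        with pytest.raises(ValueError, match="zero edges"):
            gc.build_graph(np.zeros((4, 4)), 0.01)

    def test_degree_sum_equals_twice_edges(self, rng):
        w = rng.standard_normal((20, 20))
        w = (w + w.T) / 2
        fg = gc.build_graph(w, 0.3)
        assert sum(d for _, d in fg.graph.degree()) == 2 * fg.n_edges


class TestIsolates:
    def test_complete_graph_has_none(self, rng):
        w = np.abs(rng.standard_normal((6, 6)))
        w = (w + w.T) / 2
        assert not gc.has_isolates(gc.build_graph(w, 1.0))

    def test_suppressed_node_detected(self, rng):
        w = np.abs(rng.standard_normal((20, 20))) + 1.0
        w = (w + w.T) / 2
        w[5, :] = w[:, 5] = -10.0  # node 5 ranks below everything
        np.fill_diagonal(w, 0)
        fg = gc.build_graph(w, 0.15)
        assert gc.has_isolates(fg)
        assert fg.graph.degree(5) == 0

    def test_matches_degree_scan_oracle(self, rng):
        w = rng.standard_normal((20, 20))
        w = (w + w.T) / 2
        fg = gc.build_graph(w, 0.4)
        oracle = any(fg.graph.degree(u) == 0 for u in fg.graph)
        assert gc.has_isolates(fg) == oracle


class TestSmallWorldSigma:
    def test_random_graph_sigma_near_one(self):
        sigmas = []
        for s in range(20):
            g = nx.gnm_random_graph(50, 245, seed=s)
            if not nx.is_connected(g):
                continue
            sigmas.append(gc.small_world_sigma(g, n_random=5, seed=s))
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_lattice_with_light_rewiring_is_small_world(self):
        g = nx.watts_strogatz_graph(100, 6, 0.05, seed=1)
        assert gc.small_world_sigma(g, n_random=5, seed=0) > 1.1

    def test_complete_graph_sigma_exactly_one(self):
        g = nx.complete_graph(10)
        assert gc.small_world_sigma(g, seed=0) == 1.0

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            gc.small_world_sigma(nx.path_graph(3))


class TestSweep:
    def test_six_candidate_levels(self):
        assert len(SPARSITY_CANDIDATES) == 6
        assert SPARSITY_CANDIDATES[0] == PRIMARY_SPARSITY == 0.15
        assert np.allclose(np.diff(SPARSITY_CANDIDATES), 0.05)

    def test_sweep_reports_per_level_validity(self, desk_atlas):
        from gliomaconn.pipeline import seed_z_matrix
        p = gc.SimulationParams.desk_scale(n_subjects=2, n_volumes=120)
        cohort = gc.simulate_cohort(p, atlas=desk_atlas, mode="parcel")
        mats = [seed_z_matrix(s.parcel_series, s.seed_series["larger"])[0] for s in cohort]
        report = gc.sweep_sparsity(mats, n_random=3, seed=0)
        assert set(report.no_isolates) == set(SPARSITY_CANDIDATES)
        for lev in SPARSITY_CANDIDATES:
            assert len(report.no_isolates[lev]) == 2
            assert len(report.small_world[lev]) == 2
        assert all(lev in SPARSITY_CANDIDATES for lev in report.valid_levels)

    def test_adversarial_weak_node_fails_low_sparsity(self, rng):
        w = np.abs(rng.standard_normal((30, 30))) + 1.0
        w = (w + w.T) / 2
        w[7, :] = w[:, 7] = -5.0
        np.fill_diagonal(w, 0)
        report = gc.sweep_sparsity([w], candidates=(0.15,), n_random=2, seed=0)
        assert report.no_isolates[0.15] == [False]
        assert report.valid_levels == []


class TestNodalMetrics:
    def test_star_center_and_leaf(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0  # star with center 0
        fg = gc.build_graph(w, 4 / 10)  # K = 4 edges
        center = gc.nodal_metrics(fg, 0)
        assert center["degree"] == 1.0
        assert center["betweenness"] == 1.0
        assert center["clustering"] == 0.0
        leaf = gc.nodal_metrics(fg, 3)
        assert leaf["degree"] == 0.25
        assert leaf["betweenness"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        w = rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        fg = gc.build_graph(w, float(rng.uniform(0.3, 0.8)))
        adj = graph_to_adj(fg.graph, n)
        nodal = gc.all_nodal_metrics(fg)
        for v in range(n):
            row = gc.nodal_metrics(fg, v)
            assert row["degree"] == pytest.approx(sum(adj[v]) / (n - 1), abs=1e-12)
            assert row["betweenness"] == pytest.approx(betweenness_oracle(adj, v), abs=1e-12)
            assert row["closeness"] == pytest.approx(closeness_oracle(adj, v), abs=1e-12)
            assert row["clustering"] == pytest.approx(clustering_oracle(adj, v), abs=1e-12)
            # single-node path agrees with the all-node computation
            assert row["betweenness"] == pytest.approx(
                nodal.betweenness_centrality[v], abs=1e-12)

    def test_missing_node_rejected(self):
        fg = gc.build_graph(np.ones((4, 4)) - np.eye(4), 1.0)
        with pytest.raises(ValueError):
            gc.nodal_metrics(fg, 99)


class TestSeedDegreeRecovery:
    def test_larger_seed_outranks_smaller_in_most_subjects(self, desk_atlas):
        """With a coupling gap, the larger lesion's degree centrality wins."""
        from gliomaconn.pipeline import seed_z_matrix
        p = gc.SimulationParams.desk_scale(n_subjects=12, seed=9)
        cohort = gc.simulate_cohort(p, atlas=desk_atlas, mode="parcel")
        wins = 0
        for s in cohort:
            degs = {}
            for st in ("larger", "smaller"):
                z, _ = seed_z_matrix(s.parcel_series, s.seed_series[st])
                fg = gc.build_graph(z, PRIMARY_SPARSITY)
                degs[st] = gc.nodal_metrics(fg, z.shape[0] - 1)["degree"]
            wins += degs["larger"] >= degs["smaller"]
        assert wins / len(cohort) >= 0.8
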