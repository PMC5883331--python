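"""Graph-topology battery against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from transcortex.atlas import ParcelAtlas
from transcortex.networks import BinaryGraph
from transcortex.topology import (degree_and_distance, global_metrics,
                                  participation_coefficient, rewire_null,
                                  rich_club, small_worldness)


def _graph(adj):
    return BinaryGraph(adjacency=np.asarray(adj, bool), density=0.0)


def _random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    return _graph(adj)


# ------------------------------------------------------- oracle helpers

def _bfs_distances(adj):
    n = len(adj)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def oracle_metrics(adj):
    """Brute-force Cp, Lp, Eglob, Eloc, assortativity."""
    n = len(adj)
    deg = adj.sum(0)
    # clustering: triangles over connected triples per node
    cps = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            cps.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        cps.append(2 * links / (k * (k - 1)))
    cp = float(np.mean(cps))
    dist = _bfs_distances(adj)
    finite, inv, cnt = [], 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cnt += 1
            if np.isfinite(dist[i, j]):
                finite.append(dist[i, j])
                inv += 1 / dist[i, j]
    lp = float(np.mean(finite))
    eglob = inv / cnt

    def sub_eglob(nodes):
        sub = adj[np.ix_(nodes, nodes)]
        sd = _bfs_distances(sub)
        m = len(nodes)
        tot = 0.0
        for i in range(m):
            for j in range(m):
                if i != j and np.isfinite(sd[i, j]):
                    tot += 1 / sd[i, j]
        return tot / (m * (m - 1))

    elocs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        elocs.append(sub_eglob(nbrs) if len(nbrs) >= 2 else 0.0)
    eloc = float(np.mean(elocs))

    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    a = float(np.corrcoef(xs, ys)[0, 1]) if xs.std() > 0 else np.nan
    return cp, lp, eglob, eloc, a


def oracle_phi(adj, k):
    deg = adj.sum(0)
    nodes = np.flatnonzero(deg > k)
    if len(nodes) < 2:
        return np.nan
    e = 0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if adj[nodes[a], nodes[b]]:
                e += 1
    return 2 * e / (len(nodes) * (len(nodes) - 1))


# ------------------------------------------------------------- tests

def test_complete_graph_metrics():
    adj = ~np.eye(5, dtype=bool)
    gm = global_metrics(_graph(adj))
    assert gm.cp == pytest.approx(1.0)
    assert gm.lp == pytest.approx(1.0)
    assert gm.eglob == pytest.approx(1.0)


def test_star_graph_metrics():
    adj = np.zeros((5, 5), bool)
    adj[0, 1:] = adj[1:, 0] = True
    gm = global_metrics(_graph(adj))
    assert gm.cp == pytest.approx(0.0)
    # 4 pairs at distance 1, 6 at distance 2 -> Lp = (4 + 12)/10 = 1.6
    assert gm.lp == pytest.approx(1.6)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_bruteforce_oracle(seed):
    g = _random_graph(20, 0.25, seed)
    gm = global_metrics(g)
    cp, lp, eglob, eloc, a = oracle_metrics(g.adjacency)
    assert gm.cp == pytest.approx(cp, abs=1e-10)
    assert gm.lp == pytest.approx(lp, abs=1e-10)
    assert gm.eglob == pytest.approx(eglob, abs=1e-10)
    assert gm.eloc == pytest.approx(eloc, abs=1e-10)
    assert gm.assortativity == pytest.approx(a, abs=1e-10)


def test_label_permutation_leaves_global_metrics_unchanged(rng):
    g = _random_graph(18, 0.3, 99)
    perm = rng.permutation(18)
    gp = _graph(g.adjacency[np.ix_(perm, perm)])
    m1, m2 = global_metrics(g), global_metrics(gp)
    for k in ("cp", "lp", "eglob", "eloc", "assortativity"):
        assert getattr(m1, k) == pytest.approx(getattr(m2, k), abs=1e-12)


def test_rewire_preserves_degrees_and_is_reproducible():
    g = _random_graph(30, 0.2, 3)
    nulls = rewire_null(g, n=5, seed=17)
    for null in nulls.graphs:
        np.testing.assert_array_equal(np.sort(null.adjacency.sum(0)),
                                      np.sort(g.adjacency.sum(0)))
        # and exact per-node degrees, not just the sorted sequence
        np.testing.assert_array_equal(null.adjacency.sum(0),
                                      g.adjacency.sum(0))
    again = rewire_null(g, n=5, seed=17)
    for a, b in zip(nulls.graphs, again.graphs):
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


def test_triangle_cannot_rewire():
    adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], bool)
    nulls = rewire_null(_graph(adj), n=3, seed=0)
    for null in nulls.graphs:
        np.testing.assert_array_equal(null.adjacency, adj)


def test_sigma_one_when_nulls_equal_graph():
    adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], bool)
    g = _graph(adj)
    nulls = rewire_null(g, n=5, seed=0)
    assert small_worldness(g, nulls) == pytest.approx(1.0)


def test_ring_lattice_is_small_world_relative_to_nulls():
    g = nx.watts_strogatz_graph(50, 4, 0.0, seed=1)
    adj = nx.to_numpy_array(g).astype(bool)
    graph = _graph(adj)
    nulls = rewire_null(graph, n=20, seed=2)
    assert small_worldness(graph, nulls) > 1.5


def test_rich_club_complete_graph():
    adj = ~np.eye(8, dtype=bool)
    g = _graph(adj)
    nulls = rewire_null(g, n=3, seed=0)
    rc = rich_club(g, nulls)
    valid = ~np.isnan(rc.phi)
    assert np.allclose(rc.phi[valid], 1.0)


def test_rich_club_matches_oracle_on_random_graph():
    g = _random_graph(25, 0.3, 8)
    nulls = rewire_null(g, n=3, seed=1)
    rc = rich_club(g, nulls)
    for idx, k in enumerate(rc.k):
        expect = oracle_phi(g.adjacency, k)
        if np.isnan(expect):
            assert np.isnan(rc.phi[idx])
        else:
            assert rc.phi[idx] == pytest.approx(expect, abs=1e-12)


def test_rich_club_nondecreasing_when_core_is_clique():
    # periphery of degree-1 nodes attached to a 5-clique
    n = 10
    adj = np.zeros((n, n), bool)
    for i in range(5):
        for j in range(i + 1, 5):
            adj[i, j] = adj[j, i] = True
    for leaf, hub in zip(range(5, 10), range(5)):
        adj[leaf, hub] = adj[hub, leaf] = True
    g = _graph(adj)
    nulls = rewire_null(g, n=2, seed=0)
    rc = rich_club(g, nulls)
    phis = rc.phi[~np.isnan(rc.phi)]
    assert (np.diff(phis) >= -1e-12).all()


def test_normalized_rich_club_near_one_for_er_graph():
    g = _random_graph(40, 0.3, 21)
    nulls = rewire_null(g, n=60, seed=5)
    rc = rich_club(g, nulls)
    deg = g.degree()
    for idx, k in enumerate(rc.k):
        if (deg > k).sum() >= 10 and np.isfinite(rc.rho_norm[idx]) \
                and rc.null_sd[idx] > 0:
            assert abs(rc.phi[idx] - rc.phi_rand[idx]) <= 3 * rc.null_sd[idx]


def _line_atlas(n):
    cents = np.column_stack([-np.arange(1.0, n + 1), np.zeros(n),
                             np.zeros(n)])
    adj = np.zeros((n, n), bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return ParcelAtlas(region_id=np.arange(1, n + 1), centroids=cents,
                       adjacency=adj, hemisphere=np.array(["L"] * n),
                       ve_class=np.ones(n, int))


def test_edge_distance_three_four_five():
    cents = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
    atlas = ParcelAtlas(region_id=np.array([1, 2]), centroids=cents,
                        adjacency=np.array([[False, True], [True, False]]),
                        hemisphere=np.array(["L", "L"]),
                        ve_class=np.ones(2, int))
    adj = np.array([[0, 1], [1, 0]], bool)
    nodal, edges = degree_and_distance(_graph(adj), atlas)
    assert edges["distance_mm"].iloc[0] == pytest.approx(5.0)


def test_mean_connection_distance():
    # hub at origin, leaves at distances 2, 4, 6
    cents = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 4.0, 0], [0, 0, 6.0]])
    adj = np.zeros((4, 4), bool)
    adj[0, 1:] = adj[1:, 0] = True
    atlas = ParcelAtlas(region_id=np.arange(1, 5), centroids=cents,
                        adjacency=adj, hemisphere=np.array(["L"] * 4),
                        ve_class=np.ones(4, int))
    nodal, _ = degree_and_distance(_graph(adj), atlas)
    assert nodal["mean_distance_mm"].iloc[0] == pytest.approx(4.0)


def test_distance_table_matches_double_loop(atlas60):
    left = atlas60.left()
    g = _random_graph(left.n_regions, 0.1, 13)
    nodal, edges = degree_and_distance(g, left)
    for _, row in edges.head(40).iterrows():
        i = np.flatnonzero(left.region_id == row["region_i"])[0]
        j = np.flatnonzero(left.region_id == row["region_j"])[0]
        d = np.sqrt(((left.centroids[i] - left.centroids[j]) ** 2).sum())
        assert row["distance_mm"] == pytest.approx(d, abs=1e-10)


def test_participation_coefficient_limits_and_oracle(rng):
    adj = np.zeros((6, 6), bool)
    # node 0: all 4 neighbors in its own module -> P = 0
    for j in (1, 2, 3, 4):
        adj[0, j] = adj[j, 0] = True
    labels_own = np.array([1, 1, 1, 1, 1, 2])
    p = participation_coefficient(_graph(adj), labels_own)
    assert p[0] == pytest.approx(0.0)
    # node 0: 2 neighbors in each of 2 modules -> P = 0.5
    labels_split = np.array([1, 1, 1, 2, 2, 2])
    p = participation_coefficient(_graph(adj), labels_split)
    assert p[0] == pytest.approx(0.5)
    # isolated node -> 0
    assert p[5] == 0.0
    # random graph against per-module counting
    g = _random_graph(15, 0.3, 31)
    labels = rng.integers(1, 4, 15)
    p = participation_coefficient(g, labels)
    for i in range(15):
        ki = g.adjacency[i].sum()
        if ki == 0:
            assert p[i] == 0.0
            continue
        s = 0.0
        for mod in np.unique(labels):
            kis = sum(1 for j in np.flatnonzero(g.adjacency[i])
                      if labels[j] == mod)
            s += (kis / ki) ** 2
        assert p[i] == pytest.approx(1 - s, abs=1e-12)
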