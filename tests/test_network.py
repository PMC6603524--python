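import itertools
import math

import numpy as np
import pytest

from tremornet.embedding import EmbeddingParams, embed
from tremornet.io import ValidationError
from tremornet.network import (RecurrenceNetwork, assortativity, build_network,
                               epsilon_for_rr, global_clustering,
                               measures_for_points, network_measures,
                               transitivity)


# ---------------------------------------------------------------------------
# brute-force oracles (naive enumeration; deliberately slow and obvious)
# ---------------------------------------------------------------------------

def brute_clustering(a):
    n = len(a)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u][v])
        total += 2.0 * links / (k * (k - 1))
    return total / n


def brute_transitivity(a):
    n = len(a)
    triangles = triples = 0
    for i, j, q in itertools.combinations(range(n), 3):
        edges = int(a[i][j]) + int(a[j][q]) + int(a[i][q])
        if edges == 3:
            triangles += 1
        # each pair of edges sharing a vertex is one connected triple
    for i in range(n):
        k = sum(int(a[i][j]) for j in range(n))
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def brute_assortativity(a):
    n = len(a)
    deg = [sum(int(a[i][j]) for j in range(n)) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if a[i][j] and i != j:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return float("nan")
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) /
                 (xs.std() * ys.std()))


def random_adjacency(rng, n, p):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


# ---------------------------------------------------------------------------


class TestEpsilonForRR:
    def test_path_graph_from_line(self):
        pts = np.arange(10.0)[:, None]
        # 9 of 45 pairs have distance 1; rr=0.2 admits exactly those
        eps = epsilon_for_rr(pts, rr=0.2)
        assert 1.0 <= eps < 2.0
        net = build_network(pts, eps)
        assert net.adjacency.sum() == 2 * 9  # a path on 10 vertices

    def test_high_rate_gives_complete_graph(self, rng):
        pts = rng.standard_normal((20, 3))
        eps = epsilon_for_rr(pts, rr=0.999)
        net = build_network(pts, eps)
        assert net.adjacency.sum() == 20 * 19

    def test_identical_points_error(self):
        with pytest.raises(ValidationError):
            epsilon_for_rr(np.ones((10, 2)), 0.03)

    def test_achieved_rate_close(self, rng):
        pts = rng.standard_normal((200, 3))
        eps = epsilon_for_rr(pts, rr=0.03)
        net = build_network(pts, eps)
        assert 0.025 <= net.achieved_rr <= 0.035

    def test_monotone_and_nested(self, rng):
        pts = rng.standard_normal((60, 2))
        eps1 = epsilon_for_rr(pts, 0.02)
        eps2 = epsilon_for_rr(pts, 0.2)
        assert eps1 <= eps2
        a1 = build_network(pts, eps1).adjacency
        a2 = build_network(pts, eps2).adjacency
        assert np.all(a2[a1 == 1] == 1)  # edge set nested


class TestBuildNetwork:
    def test_identical_points_complete(self):
        net = build_network(np.zeros((3, 2)), epsilon=0.5)
        assert net.adjacency.sum() == 6

    def test_far_points_empty(self):
        net = build_network(np.array([[0.0], [10.0], [20.0]]), epsilon=5)
        assert net.adjacency.sum() == 0

    def test_boundary_is_recurrent(self):
        # Heaviside theta(0) = 1: distance exactly epsilon counts
        net = build_network(np.array([[0.0], [1.0]]), epsilon=1.0)
        assert net.adjacency[0, 1] == 1

    def test_matches_naive_double_loop(self, rng):
        pts = rng.standard_normal((40, 3))
        eps = 0.8
        net = build_network(pts, eps)
        for i in range(40):
            for j in range(40):
                d = np.max(np.abs(pts[i] - pts[j]))
                expected = 1.0 if (i != j and d <= eps) else 0.0
                assert net.adjacency[i, j] == expected

    def test_theiler_window(self, rng):
        pts = rng.standard_normal((30, 2))
        net = build_network(pts, 5.0, theiler=2)
        idx = np.arange(30)
        mask = np.abs(idx[:, None] - idx[None, :]) <= 2
        assert np.all(net.adjacency[mask] == 0)

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            RecurrenceNetwork(np.array([[0, 1], [0, 0]]), 1.0, 0.5)
        with pytest.raises(ValidationError):
            RecurrenceNetwork(np.array([[1, 1], [1, 0]]), 1.0, 0.5)


class TestMeasures:
    def test_complete_graph(self):
        a = np.ones((4, 4)) - np.eye(4)
        assert global_clustering(a) == pytest.approx(1.0)
        assert transitivity(a) == pytest.approx(1.0)

    def test_star_graph(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1
        assert global_clustering(a) == 0.0
        assert transitivity(a) == 0.0
        assert assortativity(a) == pytest.approx(-1.0)

    def test_single_triangle_and_path(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        assert transitivity(tri) == pytest.approx(1.0)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert transitivity(path) == 0.0

    def test_regular_graph_assortativity_undefined(self):
        n = 6  # cycle: every vertex has degree 2
        a = np.zeros((n, n))
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
        m = network_measures(a)
        assert not m.assortativity_defined
        assert math.isnan(m.assortativity)

    def test_empty_graph(self):
        a = np.zeros((5, 5))
        m = network_measures(a)
        assert m.clustering == 0.0
        assert m.transitivity == 0.0
        assert not m.assortativity_defined

    def test_oracle_equivalence_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            a = random_adjacency(rng, n, rng.uniform(0.1, 0.6))
            m = network_measures(a)
            assert m.clustering == pytest.approx(brute_clustering(a), abs=1e-12)
            assert m.transitivity == pytest.approx(brute_transitivity(a), abs=1e-12)
            ba = brute_assortativity(a)
            if math.isnan(ba):
                assert not m.assortativity_defined
            else:
                assert m.assortativity == pytest.approx(ba, abs=1e-12)

    def test_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.3, seed=seed)
            a = nx.to_numpy_array(g)
            assert global_clustering(a) == pytest.approx(
                nx.average_clustering(g), abs=1e-12)
            assert transitivity(a) == pytest.approx(
                nx.transitivity(g), abs=1e-12)
            try:
                r = nx.degree_assortativity_coefficient(g)
            except Exception:
                r = float("nan")
            mine = assortativity(a)
            if not math.isnan(r):
                assert mine == pytest.approx(r, abs=1e-8)

    def test_relabelling_invariance(self, rng):
        a = random_adjacency(rng, 25, 0.3)
        perm = rng.permutation(25)
        b = a[np.ix_(perm, perm)]
        assert global_clustering(a) == pytest.approx(global_clustering(b), abs=1e-12)
        assert transitivity(a) == pytest.approx(transitivity(b), abs=1e-12)
        ra, rb = assortativity(a), assortativity(b)
        assert (math.isnan(ra) and math.isnan(rb)) or ra == pytest.approx(rb, abs=1e-12)

    def test_ranges(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 20, rng.uniform(0.05, 0.9))
            m = network_measures(a)
            assert 0 <= m.clustering <= 1
            assert 0 <= m.transitivity <= 1
            if m.assortativity_defined:
                assert -1 - 1e-12 <= m.assortativity <= 1 + 1e-12


class TestStructuredVsNoise:
    def test_periodic_signal_raises_transitivity(self):
        """A noiseless oscillation yields a denser-triangled network than
        amplitude-matched i.i.d. noise at equal recurrence rate."""
        n = 400
        t = np.arange(n)
        sine = np.sin(2 * np.pi * t / 25.1)
        noise = np.random.default_rng(7).standard_normal(n)
        noise *= sine.std() / noise.std()
        params = EmbeddingParams(tau=6, m=3)
        m_sine, _ = measures_for_points(embed(sine, params), rr=0.03)
        m_noise, _ = measures_for_points(embed(noise, params), rr=0.03)
        assert m_sine.transitivity > m_noise.transitivity
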