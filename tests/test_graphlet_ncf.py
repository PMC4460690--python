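"""Graphlet catalog, GDV counting and GDV similarity.

The counting path is validated against an independent brute-force oracle:
enumerate every node subset, keep connected induced subgraphs, classify by
explicit isomorphism against the catalog, and read the node's orbit off an
explicit isomorphism mapping.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netalign import (
    Network,
    compute_gdv,
    enumerate_graphlets,
    gdv_cost_matrix,
    gdv_similarity,
    orbit_weights,
)
from netalign.graphlet_ncf import ORBIT_COUNTS, SIZE_LEVELS

from conftest import random_network


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _catalog_graphs(max_size):
    catalog = enumerate_graphlets(max_size)
    graphs = []
    for g in catalog.graphlets:
        gg = nx.Graph()
        gg.add_nodes_from(range(g.n))
        gg.add_edges_from(g.edges)
        graphs.append((g, gg))
    return catalog, graphs


def brute_force_gdv(net: Network, size: str) -> np.ndarray:
    """Independent GDV: subset enumeration + explicit isomorphism tests."""
    max_size = SIZE_LEVELS[size]
    catalog, graphs = _catalog_graphs(max_size)
    labels = net.nodes
    counts = np.zeros((len(labels), catalog.n_orbits), dtype=int)
    index = {lab: i for i, lab in enumerate(labels)}
    for k in range(2, max_size + 1):
        for subset in itertools.combinations(labels, k):
            sub = net.graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for g, gg in graphs:
                if g.n != k or not nx.is_isomorphic(sub, gg):
                    continue
                iso = next(nx.vf2pp_all_isomorphisms(sub, gg))
                for node, pos in iso.items():
                    counts[index[node], g.node_orbit[pos]] += 1
                break
    return counts


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def test_catalog_counts_per_size():
    expected = {2: (1, 1), 3: (2, 3), 4: (6, 11), 5: (21, 58)}
    catalog = enumerate_graphlets(5)
    assert len(catalog.graphlets) == 30
    assert catalog.n_orbits == 73
    for n, (n_graphlets, n_orbits) in expected.items():
        assert sum(1 for g in catalog.graphlets if g.n == n) == n_graphlets
        lo, hi = catalog.size_boundaries()[n]
        assert hi - lo == n_orbits
    # normative boundaries: 0 | 1-3 | 4-14 | 15-72
    assert catalog.size_boundaries() == {2: (0, 1), 3: (1, 4), 4: (4, 15), 5: (15, 73)}


@pytest.mark.parametrize("max_size,n_graphlets,n_orbits", [(2, 1, 1), (3, 3, 4), (4, 9, 15)])
def test_catalog_truncated_sizes(max_size, n_graphlets, n_orbits):
    catalog = enumerate_graphlets(max_size)
    assert len(catalog.graphlets) == n_graphlets
    assert catalog.n_orbits == n_orbits


def test_catalog_rejects_bad_size():
    with pytest.raises(ValueError):
        enumerate_graphlets(6)
    with pytest.raises(ValueError):
        enumerate_graphlets(1)


def test_orbits_partition_each_graphlet():
    catalog = enumerate_graphlets(5)
    for g in catalog.graphlets:
        assert len(g.node_orbit) == g.n
        assert all(o >= 0 for o in g.node_orbit)
        # orbit ids of one graphlet are contiguous and exclusive to it
        for o in g.node_orbit:
            assert catalog.orbit_graphlet[o] == g.index


# ---------------------------------------------------------------------------
# GDV counting
# ---------------------------------------------------------------------------


def test_gdv_triangle(triangle):
    v = compute_gdv(triangle, "T4").vector("a")
    expected = np.zeros(73, dtype=int)
    expected[0], expected[3] = 2, 1
    assert np.array_equal(v, expected)


def test_gdv_single_edge():
    net = Network("e", "ab", [("a", "b")])
    v = compute_gdv(net, "T4").vector("a")
    assert v[0] == 1 and v.sum() == 1


def test_gdv_path_end_and_middle(path3):
    mat = compute_gdv(path3, "T4")
    a, b = mat.vector("a"), mat.vector("b")
    assert a[0] == 1 and a[1] == 1 and a.sum() == 2
    assert b[0] == 2 and b[2] == 1 and b.sum() == 3


def test_gdv_truncation_ranges(c6):
    full = compute_gdv(c6, "T4")
    for size, k in ORBIT_COUNTS.items():
        trunc = compute_gdv(c6, size)
        assert trunc.counts.shape[1] == k
        assert np.array_equal(trunc.counts, full.counts[:, :k])
        assert np.array_equal(full.truncate(size).counts, trunc.counts)


@pytest.mark.parametrize("seed", range(6))
def test_gdv_matches_brute_force(seed):
    net = random_network(n=8 + seed % 4, p=0.35, seed=seed)
    computed = compute_gdv(net, "T4").counts
    assert np.array_equal(computed, brute_force_gdv(net, "T4"))


@pytest.mark.parametrize("seed", range(4))
def test_orbit0_equals_degree(seed):
    net = random_network(n=12, p=0.3, seed=100 + seed)
    mat = compute_gdv(net, "T4")
    for i, lab in enumerate(mat.labels):
        assert mat.counts[i, 0] == net.degree(lab)


def test_graphlet_count_conservation():
    """Sum of a graphlet's orbit counts over all nodes = n x (induced
    occurrences of that graphlet), against a whole-graph census."""
    net = random_network(n=10, p=0.4, seed=7)
    catalog, graphs = _catalog_graphs(5)
    counts = compute_gdv(net, "T4").counts
    census = {g.index: 0 for g, _ in graphs}
    for k in range(2, 6):
        for subset in itertools.combinations(net.nodes, k):
            sub = net.graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for g, gg in graphs:
                if g.n == k and nx.is_isomorphic(sub, gg):
                    census[g.index] += 1
                    break
    for g, _ in graphs:
        orbit_cols = [o for o in range(catalog.n_orbits) if catalog.orbit_graphlet[o] == g.index]
        assert counts[:, orbit_cols].sum() == g.n * census[g.index]


# ---------------------------------------------------------------------------
# weights and similarity
# ---------------------------------------------------------------------------


def test_orbit_weight_easy_cases():
    w = orbit_weights("T4")
    assert w.affect_counts[0] == 1 and w.weights[0] == 1.0
    assert w.affect_counts[1] == 2 and w.affect_counts[2] == 2
    assert w.affect_counts[3] == 2  # triangle: edge + itself
    assert np.all(w.weights > 0) and np.all(w.weights <= 1)


def test_orbit_weights_recomputed_per_truncation():
    for size, K in ORBIT_COUNTS.items():
        w = orbit_weights(size)
        assert len(w.weights) == K
        assert np.all(w.weights > 0)
    assert orbit_weights("T1").weights[0] == 1.0


def direct_formula(u, v, w):
    num = sum(
        wi * abs(math.log(ui + 1) - math.log(vi + 1)) / math.log(max(ui, vi) + 2)
        for ui, vi, wi in zip(u, v, w)
    )
    return 1 - num / sum(w)


def test_gdv_similarity_against_direct_formula(triangle, path3):
    u = compute_gdv(triangle, "T4").vector("a")
    v = compute_gdv(path3, "T4").vector("b")
    w = orbit_weights("T4").weights
    s = gdv_similarity(u, v)
    assert 0 < s < 1
    assert s == pytest.approx(direct_formula(u, v, w), abs=1e-12)


def test_gdv_similarity_properties():
    rng = np.random.default_rng(5)
    for _ in range(20):
        u = rng.integers(0, 50, size=73)
        v = rng.integers(0, 50, size=73)
        s = gdv_similarity(u, v)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(gdv_similarity(v, u))
        assert gdv_similarity(u, u) == pytest.approx(1.0)


def test_gdv_similarity_length_mismatch():
    with pytest.raises(ValueError):
        gdv_similarity(np.zeros(73), np.zeros(15))


# ---------------------------------------------------------------------------
# cost matrix
# ---------------------------------------------------------------------------


def test_gdv_cost_matrix_self_diagonal():
    net = random_network(n=6, p=0.5, seed=11)
    mat = gdv_cost_matrix(net, net, "T4")
    assert np.allclose(np.diag(mat.values), 1.0)
    assert mat.values.min() >= 0 and mat.values.max() <= 1


def test_gdv_cost_matrix_compositional():
    net1 = random_network(n=5, p=0.5, seed=21, name="a")
    net2 = random_network(n=7, p=0.4, seed=22, name="b")
    mat = gdv_cost_matrix(net1, net2, "T4")
    g1, g2 = compute_gdv(net1, "T4"), compute_gdv(net2, "T4")
    w = orbit_weights("T4")
    for i, u in enumerate(mat.rows):
        for j, v in enumerate(mat.cols):
            expect = gdv_similarity(g1.vector(u), g2.vector(v), w)
            assert mat.values[i, j] == pytest.approx(expect, abs=1e-12)


def test_gdv_cost_matrix_requires_smaller_first():
    net1 = random_network(n=8, p=0.4, seed=31, name="big")
    net2 = random_network(n=5, p=0.4, seed=32, name="small")
    with pytest.raises(ValueError):
        gdv_cost_matrix(net1, net2, "T4")
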