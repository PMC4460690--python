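"""Graphlet-based node cost function.

Graphlets are the connected simple graphs on 2-5 nodes (30 of them up to
isomorphism); each graphlet's nodes fall into automorphism orbits (73 in
total).  The graphlet degree vector (GDV) of a node counts, for each orbit,
how many induced connected subgraph occurrences touch the node at that
orbit.  Two nodes from different networks are compared with a log-scaled,
orbit-dependency-weighted GDV similarity; the full pairwise matrix is the
topological node cost function.

Neighborhood-size levels T1-T4 restrict the catalog to graphlets on up to
2, 3, 4 and 5 nodes (orbit ranges {0}, {0..3}, {0..14}, {0..72}).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .graph_io import Network
from .ncf_blend import CostMatrix

#: neighborhood-size level -> maximum graphlet size
SIZE_LEVELS: dict[str, int] = {"T1": 2, "T2": 3, "T3": 4, "T4": 5}

#: neighborhood-size level -> number of retained orbits
ORBIT_COUNTS: dict[str, int] = {"T1": 1, "T2": 4, "T3": 15, "T4": 73}


def _edge_index(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def _mask_of_edges(edges: frozenset[tuple[int, int]], pairs: list[tuple[int, int]]) -> int:
    mask = 0
    for i, pair in enumerate(pairs):
        if pair in edges:
            mask |= 1 << i
    return mask


def _permute_mask(mask: int, perm: tuple[int, ...], pairs: list[tuple[int, int]],
                  pair_pos: dict[tuple[int, int], int]) -> int:
    """Relabel a graph bitmask by ``perm`` (perm[i] = new label of node i)."""
    out = 0
    for i, (a, b) in enumerate(pairs):
        if mask >> i & 1:
            na, nb = perm[a], perm[b]
            out |= 1 << pair_pos[(na, nb) if na < nb else (nb, na)]
    return out


@lru_cache(maxsize=None)
def _canonical(mask: int, n: int) -> tuple[int, tuple[int, ...]]:
    """Minimum bitmask over all node relabelings, plus one minimizing perm."""
    pairs = _edge_index(n)
    pair_pos = {p: i for i, p in enumerate(pairs)}
    best = None
    best_perm = None
    for perm in itertools.permutations(range(n)):
        m = _permute_mask(mask, perm, pairs, pair_pos)
        if best is None or m < best:
            best, best_perm = m, perm
    return best, best_perm


def _is_connected(mask: int, n: int) -> bool:
    pairs = _edge_index(n)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, (a, b) in enumerate(pairs):
        if mask >> i & 1:
            adj[a].add(b)
            adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


@dataclass(frozen=True)
class Graphlet:
    """One canonical connected graph on 2-5 nodes."""

    index: int
    n: int
    mask: int  # adjacency bitmask in canonical labeling
    edges: tuple[tuple[int, int], ...]
    node_orbit: tuple[int, ...]  # global orbit id per canonical node


@dataclass(frozen=True)
class GraphletCatalog:
    """Ordered graphlets plus their automorphism-orbit partition.

    Ordering: by node count, then edge count, then canonical adjacency;
    orbits are numbered along graphlet order, within a graphlet by ascending
    node degree then canonical node index (so orbit 0 is the edge end,
    orbit 1 / 2 the path end / middle, orbit 3 the triangle node).
    """

    max_size: int
    graphlets: tuple[Graphlet, ...]
    n_orbits: int
    orbit_graphlet: tuple[int, ...]  # orbit id -> graphlet index
    orbit_representative: tuple[int, ...]  # orbit id -> canonical node

    def size_boundaries(self) -> dict[int, tuple[int, int]]:
        """Graphlet size -> (first orbit id, one-past-last orbit id)."""
        bounds: dict[int, tuple[int, int]] = {}
        for orbit, g_idx in enumerate(self.orbit_graphlet):
            n = self.graphlets[g_idx].n
            lo, hi = bounds.get(n, (orbit, orbit))
            bounds[n] = (min(lo, orbit), orbit + 1)
        return bounds


def _automorphism_orbits(mask: int, n: int) -> list[list[int]]:
    pairs = _edge_index(n)
    pair_pos = {p: i for i, p in enumerate(pairs)}
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in itertools.permutations(range(n)):
        if _permute_mask(mask, perm, pairs, pair_pos) == mask:
            for v in range(n):
                ra, rb = find(v), find(perm[v])
                if ra != rb:
                    parent[rb] = ra
    classes: dict[int, list[int]] = {}
    for v in range(n):
        classes.setdefault(find(v), []).append(v)
    return sorted(classes.values(), key=min)


@lru_cache(maxsize=None)
def enumerate_graphlets(max_size: int = 5) -> GraphletCatalog:
    """Enumerate all connected graphs on 2..``max_size`` nodes up to
    isomorphism, with their automorphism-orbit partitions.

    For ``max_size=5`` this yields 30 graphlets and 73 orbits.
    """
    if not 2 <= max_size <= 5:
        raise ValueError(f"max_size must be in 2..5, got {max_size}")
    graphlets: list[Graphlet] = []
    orbit_graphlet: list[int] = []
    orbit_representative: list[int] = []
    for n in range(2, max_size + 1):
        pairs = _edge_index(n)
        seen: set[int] = set()
        canon_masks: list[int] = []
        for mask in range(1 << len(pairs)):
            if not _is_connected(mask, n):
                continue
            canon, _ = _canonical(mask, n)
            if canon not in seen:
                seen.add(canon)
                canon_masks.append(canon)
        canon_masks.sort(key=lambda m: (bin(m).count("1"), m))
        for mask in canon_masks:
            g_idx = len(graphlets)
            orbits = _automorphism_orbits(mask, n)
            degree = [0] * n
            edges = []
            for i, (a, b) in enumerate(pairs):
                if mask >> i & 1:
                    degree[a] += 1
                    degree[b] += 1
                    edges.append((a, b))
            orbits.sort(key=lambda cls: (degree[cls[0]], min(cls)))
            node_orbit = [-1] * n
            for cls in orbits:
                orbit_id = len(orbit_graphlet)
                for v in cls:
                    node_orbit[v] = orbit_id
                orbit_graphlet.append(g_idx)
                orbit_representative.append(min(cls))
            graphlets.append(
                Graphlet(index=g_idx, n=n, mask=mask, edges=tuple(edges),
                         node_orbit=tuple(node_orbit))
            )
    return GraphletCatalog(
        max_size=max_size,
        graphlets=tuple(graphlets),
        n_orbits=len(orbit_graphlet),
        orbit_graphlet=tuple(orbit_graphlet),
        orbit_representative=tuple(orbit_representative),
    )


# ---------------------------------------------------------------------------
# GDV counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _orbit_lookup(max_size: int) -> dict[tuple[int, int], tuple[int, ...]]:
    """(size, canonical mask) -> orbit id per canonical node position."""
    catalog = enumerate_graphlets(max_size)
    return {(g.n, g.mask): g.node_orbit for g in catalog.graphlets}


class _OccurrenceClassifier:
    """Maps an induced-subgraph occurrence to per-node orbit ids, caching by
    the local adjacency bitmask of the occurrence."""

    def __init__(self, max_size: int) -> None:
        self._lookup = _orbit_lookup(max_size)
        self._cache: dict[tuple[int, int], tuple[int, ...]] = {}

    def orbits(self, k: int, local_mask: int) -> tuple[int, ...]:
        key = (k, local_mask)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        canon, perm = _canonical(local_mask, k)
        node_orbit = self._lookup[(k, canon)]
        # perm[i] = canonical position of local node i
        result = tuple(node_orbit[perm[i]] for i in range(k))
        self._cache[key] = result
        return result


def _connected_induced_subgraphs(adj: list[set[int]], k: int):
    """Yield every connected induced subgraph on exactly ``k`` nodes once,
    as a sorted tuple of node indices (ESU enumeration)."""
    n = len(adj)

    def extend(sub: list[int], ext: set[int], v: int):
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(ext)
        neighborhood = set().union(*(adj[u] for u in sub))
        while ext:
            w = min(ext)
            ext.remove(w)
            new_ext = ext | {u for u in adj[w] if u > v and u not in neighborhood}
            yield from extend(sub + [w], new_ext, v)

    for v in range(n):
        yield from extend([v], {u for u in adj[v] if u > v}, v)


@dataclass(frozen=True)
class GDVMatrix:
    """Per-node graphlet degree vectors.

    ``counts[i, j]`` is the number of induced occurrences touching node
    ``labels[i]`` at orbit ``j``; column 0 is the node degree.
    """

    labels: tuple[str, ...]
    counts: np.ndarray  # (n_nodes, n_orbits) ints
    size: str  # T1..T4

    def vector(self, label: str) -> np.ndarray:
        return self.counts[self.labels.index(label)]

    def truncate(self, size: str) -> "GDVMatrix":
        """Restrict to the orbit range of a smaller neighborhood size."""
        k = ORBIT_COUNTS[size]
        if k > self.counts.shape[1]:
            raise ValueError(f"cannot truncate {self.size} matrix up to {size}")
        return GDVMatrix(self.labels, self.counts[:, :k].copy(), size)


def compute_gdv(net: Network, size: str = "T4") -> GDVMatrix:
    """Compute the graphlet degree vector of every node of ``net``.

    ``size`` (T1-T4) bounds the graphlet size at 2-5 nodes.  Occurrences are
    enumerated once each over connected induced subgraphs (ESU) and each
    member node's orbit count is incremented.
    """
    if size not in SIZE_LEVELS:
        raise ValueError(f"unknown neighborhood size {size!r}")
    max_size = SIZE_LEVELS[size]
    labels = net.nodes
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in net.edges:
        ia, ib = index[a], index[b]
        adj[ia].add(ib)
        adj[ib].add(ia)

    n_orbits = ORBIT_COUNTS[size]
    counts = np.zeros((n, n_orbits), dtype=np.int64)
    classifier = _OccurrenceClassifier(max_size)
    for k in range(2, max_size + 1):
        pairs = _edge_index(k)
        for occ in _connected_induced_subgraphs(adj, k):
            local_mask = 0
            for i, (a, b) in enumerate(pairs):
                if occ[b] in adj[occ[a]]:
                    local_mask |= 1 << i
            orbits = classifier.orbits(k, local_mask)
            for pos, node in enumerate(occ):
                counts[node, orbits[pos]] += 1
    return GDVMatrix(labels, counts, size)


# ---------------------------------------------------------------------------
# orbit weights and GDV similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrbitWeights:
    """Orbit dependency weights ``w_i = 1 - log(o_i)/log(K)``.

    ``o_i`` (the affect count) is the number of distinct orbits that the
    orbit-``i`` representative node touches within its own graphlet, i.e. the
    orbits reachable as induced connected subgraphs of the graphlet that
    contain that node.  ``K`` is the number of orbits retained at the active
    neighborhood size, so deeper, more redundant orbits are down-weighted.
    When K = 1 the single orbit gets weight 1.
    """

    size: str
    affect_counts: tuple[int, ...]
    weights: np.ndarray


@lru_cache(maxsize=None)
def orbit_weights(size: str = "T4") -> OrbitWeights:
    if size not in SIZE_LEVELS:
        raise ValueError(f"unknown neighborhood size {size!r}")
    max_size = SIZE_LEVELS[size]
    catalog = enumerate_graphlets(max_size)
    classifier = _OccurrenceClassifier(max_size)
    affects: list[int] = []
    for orbit in range(catalog.n_orbits):
        g = catalog.graphlets[catalog.orbit_graphlet[orbit]]
        rep = catalog.orbit_representative[orbit]
        adj: list[set[int]] = [set() for _ in range(g.n)]
        for a, b in g.edges:
            adj[a].add(b)
            adj[b].add(a)
        touched: set[int] = set()
        pairs_by_k = {k: _edge_index(k) for k in range(2, g.n + 1)}
        for k in range(2, g.n + 1):
            for occ in _connected_induced_subgraphs(adj, k):
                if rep not in occ:
                    continue
                local_mask = 0
                for i, (a, b) in enumerate(pairs_by_k[k]):
                    if occ[b] in adj[occ[a]]:
                        local_mask |= 1 << i
                touched.add(classifier.orbits(k, local_mask)[occ.index(rep)])
        affects.append(len(touched))
    K = catalog.n_orbits
    if K == 1:
        weights = np.ones(1)
    else:
        weights = 1.0 - np.log(np.array(affects, dtype=float)) / np.log(K)
    if np.any(weights <= 0):
        raise AssertionError("orbit weights must be positive")
    return OrbitWeights(size=size, affect_counts=tuple(affects), weights=weights)


def gdv_similarity(u_vec: np.ndarray, v_vec: np.ndarray,
                   weights: OrbitWeights | None = None) -> float:
    """GDV similarity in [0, 1] between two orbit-count vectors.

    Per-orbit distance ``D_i = w_i |log(u_i+1) - log(v_i+1)| /
    log(max(u_i, v_i) + 2)``; the total distance is ``sum(D_i)/sum(w_i)`` and
    the similarity its complement.  Symmetric; 1 for identical vectors.
    """
    u = np.asarray(u_vec, dtype=float)
    v = np.asarray(v_vec, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"orbit vector length mismatch: {u.shape} vs {v.shape}")
    if weights is None:
        size = {v: k for k, v in ORBIT_COUNTS.items()}.get(u.shape[0])
        if size is None:
            raise ValueError(f"vector length {u.shape[0]} is not a T1-T4 orbit count")
        weights = orbit_weights(size)
    w = weights.weights
    if w.shape[0] != u.shape[0]:
        raise ValueError("weights do not match vector length")
    num = w * np.abs(np.log(u + 1.0) - np.log(v + 1.0))
    den = np.log(np.maximum(u, v) + 2.0)
    distance = float(np.sum(num / den) / np.sum(w))
    return 1.0 - distance


def gdv_cost_matrix(net1: Network, net2: Network, size: str = "T4") -> CostMatrix:
    """Full |V1| x |V2| GDV-similarity matrix (the graphlet NCF).

    ``net1`` must be the smaller network (fewer nodes).
    """
    if net1.number_of_nodes() > net2.number_of_nodes():
        raise ValueError("net1 must be the smaller network")
    gdv1 = compute_gdv(net1, size)
    gdv2 = compute_gdv(net2, size) if net2 is not net1 else gdv1
    w = orbit_weights(size).weights
    wsum = float(np.sum(w))
    u = gdv1.counts.astype(float)
    v = gdv2.counts.astype(float)
    log_u = np.log(u + 1.0)
    log_v = np.log(v + 1.0)
    n1 = u.shape[0]
    values = np.empty((n1, v.shape[0]))
    for i in range(n1):  # row-wise to bound memory on larger networks
        num = w * np.abs(log_u[i][None, :] - log_v)
        den = np.log(np.maximum(u[i][None, :], v) + 2.0)
        values[i] = 1.0 - np.sum(num / den, axis=1) / wsum
    return CostMatrix(rows=gdv1.labels, cols=gdv2.labels,
                      values=np.clip(values, 0.0, 1.0), provenance="topology")
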