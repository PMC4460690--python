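"""Alignment strategies: seed-and-extend over a node cost function.

Both strategies share the same skeleton.  A seed is the unaligned
cross-network pair with the highest cost (ties broken lexicographically).
Around each aligned pair (u, v) a bipartite graph is built between the
unaligned neighbors of u and of v, with an edge (x, y) iff some neighbor of
x is already aligned to some neighbor of y; an exact maximum-weight
bipartite matching decides which candidates to align, and newly aligned
pairs join the expansion frontier.  When the frontier empties, the next
best unaligned pair is re-seeded, until the whole smaller network is
mapped, so the result is always total and injective.

The two strategies differ only in the bipartite edge weight:

* linear-assignment flavor: weight = cost(x, y);
* QAP-aware flavor: weight = ``lam*cost(x, y) + (1-lam)*consistency(x, y)``
  where the consistency term compares within-network similarity profiles of
  the candidates against already-aligned anchor pairs in the local region,
  rewarding candidates whose relation to the anchors matches on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx

from .graph_io import Network
from .ncf_blend import CostMatrix


@dataclass
class Alignment:
    """Total injective node map from the smaller network into the larger."""

    mapping: dict[str, str]
    aligner: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = set(self.mapping.values())
        if len(targets) != len(self.mapping):
            raise ValueError("alignment is not injective")

    def __getitem__(self, node: str) -> str:
        return self.mapping[node]

    def __len__(self) -> int:
        return len(self.mapping)

    def items(self):
        return self.mapping.items()


@dataclass
class TruthMapping:
    """Known correct node mapping (possibly partial), injective where defined."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        targets = set(self.mapping.values())
        if len(targets) != len(self.mapping):
            raise ValueError("truth mapping is not injective")

    @classmethod
    def identity(cls, nodes: Iterable[str]) -> "TruthMapping":
        return cls({n: n for n in nodes})


def local_match(
    candidates: dict[tuple[str, str], float]
) -> set[tuple[str, str]]:
    """Exact maximum-weight matching of a weighted bipartite edge set.

    Not necessarily perfect: zero-gain edges may be left unmatched.  Nodes
    are inserted in sorted order so the result is deterministic.
    """
    if not candidates:
        return set()
    g = nx.Graph()
    for (x, y) in sorted(candidates):
        g.add_edge(("L", x), ("R", y), weight=candidates[(x, y)])
    matching = nx.max_weight_matching(g, maxcardinality=False)
    result = set()
    for a, b in matching:
        if a[0] == "R":
            a, b = b, a
        result.add((a[1], b[1]))
    return result


class _SeedExtendEngine:
    """Shared seed-and-extend machinery; the weight function is the only
    strategy-specific part."""

    def __init__(
        self,
        net1: Network,
        net2: Network,
        cost: CostMatrix,
        weight_fn: Callable[[str, str, str, str, dict[str, str]], float],
    ) -> None:
        if net1.number_of_nodes() > net2.number_of_nodes():
            raise ValueError("net1 must be the smaller network")
        if cost.rows != net1.nodes or cost.cols != net2.nodes:
            raise ValueError("cost matrix labels do not match the networks")
        self.net1 = net1
        self.net2 = net2
        self.cost = cost
        self.weight_fn = weight_fn
        self.mapping: dict[str, str] = {}
        self.used_targets: set[str] = set()

    def _best_unaligned_pair(self) -> tuple[str, str]:
        best = None
        best_score = -1.0
        for u in self.net1.nodes:
            if u in self.mapping:
                continue
            i = self.cost.row_of(u)
            for j, v in enumerate(self.cost.cols):
                if v in self.used_targets:
                    continue
                s = self.cost.values[i, j]
                if s > best_score or (s == best_score and (u, v) < best):
                    best, best_score = (u, v), s
        assert best is not None
        return best

    def _accept(self, u: str, v: str) -> None:
        self.mapping[u] = v
        self.used_targets.add(v)

    def _expand(self, u: str, v: str) -> list[tuple[str, str]]:
        cand_x = sorted(x for x in self.net1.neighbors(u) if x not in self.mapping)
        cand_y = sorted(y for y in self.net2.neighbors(v) if y not in self.used_targets)
        if not cand_x or not cand_y:
            return []
        edges: dict[tuple[str, str], float] = {}
        for x in cand_x:
            aligned_neighbors = {
                self.mapping[a] for a in self.net1.neighbors(x) if a in self.mapping
            }
            if not aligned_neighbors:
                continue
            for y in cand_y:
                if aligned_neighbors & self.net2.neighbors(y):
                    edges[(x, y)] = self.weight_fn(x, y, u, v, self.mapping)
        matched = sorted(local_match(edges))
        accepted = []
        for x, y in matched:
            if x not in self.mapping and y not in self.used_targets:
                self._accept(x, y)
                accepted.append((x, y))
        return accepted

    def run(self) -> dict[str, str]:
        n1 = self.net1.number_of_nodes()
        while len(self.mapping) < n1:
            seed = self._best_unaligned_pair()
            self._accept(*seed)
            frontier = [seed]
            while frontier:
                pair = frontier.pop(0)
                frontier.extend(self._expand(*pair))
        return self.mapping


def align_seed_extend(
    net1: Network, net2: Network, cost: CostMatrix
) -> Alignment:
    """Seed-and-extend with linear-assignment local matching.

    Bipartite candidate edges are weighted by the cross-network cost alone;
    each local step is an exact maximum-weight bipartite matching.
    """

    def weight(x: str, y: str, u: str, v: str, mapping: dict[str, str]) -> float:
        return cost.get(x, y)

    engine = _SeedExtendEngine(net1, net2, cost, weight)
    return Alignment(engine.run(), aligner="seedextend")


def align_qap(
    net1: Network,
    net2: Network,
    cost: CostMatrix,
    lam: float = 0.5,
    within1: CostMatrix | None = None,
    within2: CostMatrix | None = None,
) -> Alignment:
    """Seed-and-extend with a quadratic-assignment-aware local weight.

    The candidate weight is ``lam*cost(x, y) + (1-lam)*consistency(x, y)``.
    Consistency compares, for every already-aligned anchor pair (a, f(a))
    in the closed neighborhood of the pair being expanded, the
    within-network similarity of x to a against that of y to f(a):
    ``1 - mean |W1(x, a) - W2(y, f(a))|``.  ``within1``/``within2`` are the
    square within-network similarity matrices of the same NCF that produced
    ``cost``; with no anchors the consistency falls back to the cross cost.
    With ``lam=1`` the strategy reduces exactly to
    :func:`align_seed_extend`.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if lam < 1.0:
        if within1 is None or within2 is None:
            raise ValueError("within-network similarity matrices are required for lam < 1")
        if within1.rows != net1.nodes or within1.cols != net1.nodes:
            raise ValueError("within1 must be square over net1's nodes")
        if within2.rows != net2.nodes or within2.cols != net2.nodes:
            raise ValueError("within2 must be square over net2's nodes")

    def weight(x: str, y: str, u: str, v: str, mapping: dict[str, str]) -> float:
        c = cost.get(x, y)
        if lam == 1.0:
            return c
        anchors = [a for a in sorted({u} | net1.neighbors(u)) if a in mapping]
        if not anchors:
            consistency = c
        else:
            disc = 0.0
            for a in anchors:
                disc += abs(within1.get(x, a) - within2.get(y, mapping[a]))
            consistency = 1.0 - disc / len(anchors)
        return lam * c + (1.0 - lam) * consistency

    engine = _SeedExtendEngine(net1, net2, cost, weight)
    return Alignment(engine.run(), aligner="qap", params={"lam": lam})
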