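"""Input/output for networks, sequence scores, GO annotations and alignments.

All file formats are plain text.  Networks are undirected simple graphs with
string node labels; the universal dialect is a whitespace-separated edge list
(one edge per line, ``#`` starts a comment, a single token declares an
isolated node).  The undirected unlabeled-edge subset of the LEDA ``.gw``
dialect is also read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: GO evidence codes accepted as "experimental".
EXPERIMENTAL_EVIDENCE_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class Network:
    """Labeled undirected simple graph.

    Invariants: no self-loops, no duplicate edges ((a, b) and (b, a) are the
    same edge), and every edge endpoint is in the node set.  Node identity is
    the exact string label; all derived orderings sort labels so downstream
    computations are deterministic.
    """

    __slots__ = ("name", "_graph", "_nodes", "_edges")

    def __init__(
        self,
        name: str,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        g = nx.Graph(name=name)
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r} in network {name!r}")
            g.add_edge(a, b)
        self.name = name
        self._graph = g
        self._nodes: tuple[str, ...] = tuple(sorted(g.nodes))
        self._edges: frozenset[tuple[str, str]] = frozenset(
            (a, b) if a < b else (b, a) for a, b in g.edges
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str | None = None) -> "Network":
        name = name if name is not None else (g.name or "network")
        return cls(name, (str(n) for n in g.nodes), ((str(a), str(b)) for a, b in g.edges))

    # -- accessors ----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """Underlying :class:`networkx.Graph` (do not mutate)."""
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node labels in sorted order."""
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges as sorted label pairs."""
        return self._edges

    def number_of_nodes(self) -> int:
        return len(self._nodes)

    def number_of_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, u: str) -> set[str]:
        return set(self._graph.neighbors(u))

    def degree(self, u: str) -> int:
        return self._graph.degree(u)

    def has_edge(self, a: str, b: str) -> bool:
        return self._graph.has_edge(a, b)

    def subgraph(self, nodes: Iterable[str], name: str | None = None) -> "Network":
        sub = self._graph.subgraph(list(nodes))
        return Network.from_networkx(sub, name or f"{self.name}|sub")

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Network({self.name!r}, |V|={self.number_of_nodes()}, "
            f"|E|={self.number_of_edges()})"
        )


def smaller_first(net_a: Network, net_b: Network) -> tuple[Network, Network]:
    """Order two networks so the "smaller" one (fewer nodes; ties broken by
    fewer edges, then lexicographically smaller name) comes first."""
    ka = (net_a.number_of_nodes(), net_a.number_of_edges(), net_a.name)
    kb = (net_b.number_of_nodes(), net_b.number_of_edges(), net_b.name)
    return (net_a, net_b) if ka <= kb else (net_b, net_a)


@dataclass
class PairScoreTable:
    """Sparse non-negative scores on cross-network node pairs.

    Typical content: BLAST bit scores between proteins of two species.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, score in self.entries.items():
            if score < 0:
                raise ValueError(f"negative score {score} for pair {pair}")

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.entries.get((a, b), default)

    def max_score(self) -> float:
        if not self.entries:
            raise ValueError("empty score table has no maximum")
        return max(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnnotationMap:
    """Protein label -> set of (GO term, evidence code) pairs."""

    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def terms(self, protein: str) -> set[str]:
        return {term for term, _ in self.annotations.get(protein, set())}

    def is_annotated(self, protein: str) -> bool:
        return bool(self.annotations.get(protein))

    def experimental_only(self) -> "AnnotationMap":
        filtered = {
            p: {(t, ev) for t, ev in anns if ev in EXPERIMENTAL_EVIDENCE_CODES}
            for p, anns in self.annotations.items()
        }
        return AnnotationMap({p: a for p, a in filtered.items() if a})


# ---------------------------------------------------------------------------
# network readers / writers
# ---------------------------------------------------------------------------


def _parse_edgelist(lines: list[str], name: str) -> Network:
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    seen_any = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        seen_any = True
        tokens = line.split()
        if len(tokens) == 1:
            nodes.add(tokens[0])
        elif len(tokens) == 2:
            a, b = tokens
            if a == b:
                logger.warning("%s:%d: dropping self-loop %r", name, lineno, a)
                nodes.add(a)
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                logger.warning("%s:%d: dropping duplicate edge %s-%s", name, lineno, a, b)
            edges.add(key)
            nodes.update(key)
        else:
            raise ValueError(f"{name}:{lineno}: malformed edge line {raw!r}")
    if not seen_any:
        raise ValueError(f"{name}: empty network file")
    return Network(name, nodes, edges)


def _parse_leda_gw(lines: list[str], name: str) -> Network:
    # LEDA.GRAPH / value types / directedness / n / node lines / m / edge lines
    body = [ln.rstrip("\n") for ln in lines]
    if not body or not body[0].startswith("LEDA.GRAPH"):
        raise ValueError(f"{name}:1: missing LEDA.GRAPH header")
    idx = 3  # skip header + two value-type lines
    if idx >= len(body):
        raise ValueError(f"{name}: truncated LEDA file")
    # optional directedness marker (-1 undirected, -2 directed)
    if body[idx].strip() in {"-1", "-2"}:
        if body[idx].strip() == "-2":
            raise ValueError(f"{name}: directed LEDA graphs are not supported")
        idx += 1
    try:
        n = int(body[idx].strip())
    except ValueError as exc:
        raise ValueError(f"{name}:{idx + 1}: expected node count") from exc
    idx += 1
    labels: list[str] = []
    for i in range(n):
        line = body[idx + i].strip()
        if not (line.startswith("|{") and line.endswith("}|")):
            raise ValueError(f"{name}:{idx + i + 1}: malformed node line {line!r}")
        labels.append(line[2:-2])
    idx += n
    try:
        m = int(body[idx].strip())
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{name}:{idx + 1}: expected edge count") from exc
    idx += 1
    edges: set[tuple[str, str]] = set()
    for i in range(m):
        tokens = body[idx + i].split()
        if len(tokens) < 2:
            raise ValueError(f"{name}:{idx + i + 1}: malformed edge line")
        s, t = int(tokens[0]) - 1, int(tokens[1]) - 1
        if not (0 <= s < n and 0 <= t < n):
            raise ValueError(f"{name}:{idx + i + 1}: edge endpoint out of range")
        a, b = labels[s], labels[t]
        if a == b:
            logger.warning("%s:%d: dropping self-loop %r", name, idx + i + 1, a)
            continue
        edges.add((a, b) if a < b else (b, a))
    return Network(name, labels, edges)


def read_network(path: str | Path, format: str = "edgelist") -> Network:
    """Read a network from ``path``.

    ``format`` is ``edgelist`` (whitespace-separated pairs, ``#`` comments,
    lone tokens declare isolated nodes) or ``leda_gw``.
    """
    path = Path(path)
    name = path.stem
    lines = path.read_text().splitlines()
    if format == "edgelist":
        return _parse_edgelist(lines, name)
    if format == "leda_gw":
        return _parse_leda_gw(lines, name)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: Network, path: str | Path, format: str = "edgelist") -> None:
    path = Path(path)
    if format == "edgelist":
        out = []
        isolated = set(net.nodes) - {n for e in net.edges for n in e}
        for a, b in sorted(net.edges):
            out.append(f"{a}\t{b}")
        for n in sorted(isolated):
            out.append(n)
        path.write_text("\n".join(out) + "\n")
    elif format == "leda_gw":
        labels = list(net.nodes)
        index = {lab: i + 1 for i, lab in enumerate(labels)}
        out = ["LEDA.GRAPH", "string", "short", "-1", str(len(labels))]
        out += [f"|{{{lab}}}|" for lab in labels]
        out.append(str(net.number_of_edges()))
        out += [f"{index[a]} {index[b]} 0 |{{}}|" for a, b in sorted(net.edges)]
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# score / annotation / alignment tables
# ---------------------------------------------------------------------------


def read_pair_scores(path: str | Path) -> PairScoreTable:
    """Read TSV triplets ``labelA labelB score`` (e.g. BLAST bit scores)."""
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise ValueError(f"{path.name}:{lineno}: expected 'labelA labelB score'")
        a, b, score_s = tokens
        try:
            score = float(score_s)
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-numeric score {score_s!r}") from exc
        if score < 0:
            raise ValueError(f"{path.name}:{lineno}: negative score {score}")
        if (a, b) in entries:
            logger.warning("%s:%d: duplicate pair (%s, %s); last value wins", path.name, lineno, a, b)
        entries[(a, b)] = score
    return PairScoreTable(entries)


def write_pair_scores(table: PairScoreTable, path: str | Path) -> None:
    lines = [f"{a}\t{b}\t{s:.10g}" for (a, b), s in sorted(table.entries.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path: str | Path, experimental_only: bool = False) -> AnnotationMap:
    """Read TSV ``protein GOterm [evidence_code]`` rows.

    With ``experimental_only`` set, only annotations carrying an experimental
    evidence code (EXP, IDA, IPI, IMP, IGI, IEP) are kept.
    """
    path = Path(path)
    annotations: dict[str, set[tuple[str, str]]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path.name}:{lineno}: missing GO term column")
        protein, term = tokens[0], tokens[1]
        evidence = tokens[2] if len(tokens) > 2 else ""
        if not term:
            raise ValueError(f"{path.name}:{lineno}: empty GO term")
        annotations.setdefault(protein, set()).add((term, evidence))
    result = AnnotationMap(annotations)
    return result.experimental_only() if experimental_only else result


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    lines = [
        f"{p}\t{term}\t{ev}".rstrip()
        for p in sorted(ann.annotations)
        for term, ev in sorted(ann.annotations[p])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV alignment (smaller-network node, larger-network
    node) and validate injectivity."""
    path = Path(path)
    mapping: dict[str, str] = {}
    targets: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected two columns")
        a, b = tokens
        if a in mapping:
            raise ValueError(f"{path.name}:{lineno}: repeated source node {a!r}")
        if b in targets:
            raise ValueError(f"{path.name}:{lineno}: repeated target node {b!r} (non-injective)")
        mapping[a] = b
        targets.add(b)
    return mapping


def write_alignment(mapping: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{a}\t{b}" for a, b in sorted(mapping.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
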