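"""Ground-truth benchmarking: noisy-network generation, synthetic fixtures,
the (aligner x alpha x neighborhood-size) evaluation grid, and rank /
correlation aggregation.

The noise model mirrors the classic known-mapping benchmark: starting from
a base network, each noise level x adds ``round(x/100 * |E|)`` extra edges
among the existing nodes (optionally drawn from a supplied low-confidence
edge pool), so the base network is an exact subgraph of every noisy variant
and the identity mapping is the ground truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import Alignment, TruthMapping, align_qap, align_seed_extend
from .graph_io import (
    AnnotationMap,
    Network,
    PairScoreTable,
    write_alignment,
    write_annotations,
    write_network,
    write_pair_scores,
)
from .graphlet_ncf import compute_gdv, gdv_cost_matrix
from .ncf_blend import (
    DEFAULT_ALPHA_GRID,
    CostMatrix,
    blend,
    sequence_cost_matrix,
    topk_sparsify,
)
from .quality import QualityReport, evaluate_alignment, measure_correlations
from .spectral_ncf import HOP_LEVELS, spectral_cost_matrix

logger = logging.getLogger(__name__)

#: aligner codes: first letter NCF (M = graphlet, G = spectral), second AS
#: (M = linear-assignment seed-and-extend, G = QAP-aware seed-and-extend)
ALIGNERS = ("M-M", "G-M", "G-G", "M-G")

DEFAULT_NOISE_LEVELS = (5, 10, 15, 20, 25)
DEFAULT_SIZES = ("T1", "T2", "T3", "T4")

#: measures entering rankings and correlations
RANKED_MEASURES = ("NC", "EC", "ICS", "S3", "LCCS", "GO", "EXP")


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


def add_noise(
    base: Network,
    x: float,
    pool: Sequence[tuple[str, str]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> Network:
    """Add ``round(x/100 * |E|)`` edges to ``base`` among its own nodes.

    Extra edges are sampled uniformly without replacement from ``pool`` (a
    list of non-edges, e.g. low-confidence interactions) or, by default,
    from all non-edges.  The base network is an exact subgraph of the
    result.
    """
    if x < 0:
        raise ValueError(f"noise level must be >= 0, got {x}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_extra = round(x / 100.0 * base.number_of_edges())
    if n_extra == 0:
        return Network(f"{base.name}+{x:g}%", base.nodes, base.edges)
    if pool is not None:
        candidates = []
        for a, b in pool:
            key = (a, b) if a < b else (b, a)
            if a == b or key in base.edges or a not in base or b not in base:
                raise ValueError(f"pool edge {a}-{b} is not a non-edge of the base network")
            candidates.append(key)
        candidates = sorted(set(candidates))
    else:
        candidates = [
            (a, b)
            for a, b in itertools.combinations(base.nodes, 2)
            if (a, b) not in base.edges
        ]
    if len(candidates) < n_extra:
        raise ValueError(
            f"noise pool too small: need {n_extra} edges, have {len(candidates)}"
        )
    chosen = rng.choice(len(candidates), size=n_extra, replace=False)
    extra = [candidates[i] for i in sorted(chosen)]
    return Network(f"{base.name}+{x:g}%", base.nodes, set(base.edges) | set(extra))


def relabel_network(
    net: Network,
    rng: np.random.Generator | int | None = None,
    prefix: str = "m",
) -> tuple[Network, TruthMapping]:
    """Randomly relabel a network's nodes; returns the relabeled network and
    the old->new mapping as ground truth.

    Aligning a network against a relabeled (noisy) copy is the honest form
    of the known-mapping benchmark: node labels then carry no information,
    so deterministic tie-breaking cannot leak the truth.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = net.number_of_nodes()
    perm = rng.permutation(n)
    new_label = {old: f"{prefix}{perm[i]:03d}" for i, old in enumerate(net.nodes)}
    relabeled = Network(
        f"{net.name}|relabel",
        new_label.values(),
        ((new_label[a], new_label[b]) for a, b in net.edges),
    )
    return relabeled, TruthMapping(dict(new_label))


@dataclass
class NoiseSeries:
    """A base network plus noisy supersets at several levels, with the
    identity mapping as ground truth."""

    base: Network
    levels: tuple[float, ...]
    variants: dict[float, Network]
    truth: TruthMapping

    def pairs(self) -> list[tuple[str, Network, Network]]:
        return [
            (f"{self.base.name}-vs-{x:g}%", self.base, self.variants[x])
            for x in self.levels
        ]


def make_noise_series(
    base: Network,
    levels: Iterable[float] = DEFAULT_NOISE_LEVELS,
    pool: Sequence[tuple[str, str]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> NoiseSeries:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    levels = tuple(levels)
    variants = {x: add_noise(base, x, pool=pool, rng=rng) for x in levels}
    return NoiseSeries(
        base=base,
        levels=levels,
        variants=variants,
        truth=TruthMapping.identity(base.nodes),
    )


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def _label(i: int, width: int = 3) -> str:
    return f"n{i:0{width}d}"


def make_cycle(k: int, name: str = "cycle") -> Network:
    if k < 3:
        raise ValueError("a cycle needs at least 3 nodes")
    nodes = [_label(i) for i in range(k)]
    edges = [(nodes[i], nodes[(i + 1) % k]) for i in range(k)]
    return Network(f"{name}{k}", nodes, edges)


def make_path(k: int, name: str = "path") -> Network:
    if k < 2:
        raise ValueError("a path needs at least 2 nodes")
    nodes = [_label(i) for i in range(k)]
    return Network(f"{name}{k}", nodes, zip(nodes, nodes[1:]))


def make_clique(k: int, name: str = "clique") -> Network:
    if k < 2:
        raise ValueError("a clique needs at least 2 nodes")
    nodes = [_label(i) for i in range(k)]
    return Network(f"{name}{k}", nodes, itertools.combinations(nodes, 2))


def _is_asymmetric(g: nx.Graph) -> bool:
    isos = nx.vf2pp_all_isomorphisms(g, g)
    next(isos)  # identity always exists
    return next(isos, None) is None


def make_er_random(
    n: int, p: float, rng: np.random.Generator | int | None = None, name: str = "er"
) -> Network:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nodes = [_label(i) for i in range(n)]
    edges = [
        (a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < p
    ]
    return Network(f"{name}{n}", nodes, edges)


def make_asymmetric_tree(
    n: int, rng: np.random.Generator | int | None = None, max_tries: int = 1000
) -> Network:
    """Random tree with a trivial automorphism group (verified)."""
    if n < 6:
        raise ValueError("asymmetric trees need at least 6 nodes")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nodes = [_label(i) for i in range(n)]
    for _ in range(max_tries):
        # random attachment tree
        edges = [
            (nodes[int(rng.integers(i))], nodes[i]) for i in range(1, n)
        ]
        g = nx.Graph(edges)
        if _is_asymmetric(g):
            return Network(f"tree{n}", nodes, edges)
    raise RuntimeError("failed to generate an asymmetric tree")


def make_asymmetric_graph(
    n: int,
    p: float = 0.15,
    rng: np.random.Generator | int | None = None,
    distinct_gdv: bool = False,
    max_tries: int = 1000,
) -> Network:
    """Connected random graph with a trivial automorphism group.

    With ``distinct_gdv`` the generator additionally requires every node to
    have a unique full-size graphlet degree vector, i.e. the nodes are fully
    distinguishable by local topology — the property a ground-truth-recovery
    benchmark needs so that the correct mapping is identifiable at all.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for _ in range(max_tries):
        net = make_er_random(n, p, rng)
        if not nx.is_connected(net.graph) or not _is_asymmetric(net.graph):
            continue
        if distinct_gdv:
            counts = compute_gdv(net, "T4").counts
            if len({tuple(row) for row in counts}) < n:
                continue
        return net
    raise RuntimeError("failed to generate an asymmetric graph")


def make_annotations(
    truth: TruthMapping,
    share_rate: float = 0.7,
    n_terms: int = 20,
    experimental_rate: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> AnnotationMap:
    """Synthetic GO-like annotations over a truth mapping: with probability
    ``share_rate`` a true pair shares a term, otherwise the two sides get
    disjoint terms; evidence codes are experimental at ``experimental_rate``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    annotations: dict[str, set[tuple[str, str]]] = {}

    def evidence() -> str:
        return "IDA" if rng.random() < experimental_rate else "IEA"

    for u, v in sorted(truth.mapping.items()):
        t = int(rng.integers(n_terms))
        if rng.random() < share_rate:
            term = f"GO:{t:07d}"
            annotations.setdefault(u, set()).add((term, evidence()))
            annotations.setdefault(v, set()).add((term, evidence()))
        else:
            annotations.setdefault(u, set()).add((f"GO:{t:07d}", evidence()))
            annotations.setdefault(v, set()).add((f"GO:{t + n_terms:07d}", evidence()))
    return AnnotationMap(annotations)


def make_seq_scores(
    truth: TruthMapping,
    family_size: int = 5,
    rng: np.random.Generator | int | None = None,
) -> PairScoreTable:
    """Synthetic BLAST-like bit scores over a truth mapping.

    Source nodes are grouped into paralog-like families of
    ``family_size``; every member of a family scores equally high against
    the true targets of all family members, so sequence alone cannot
    resolve the mapping within a family (the within-family ambiguity real
    bit scores exhibit), while topology can.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sources = sorted(truth.mapping)
    order = list(rng.permutation(len(sources)))
    entries: dict[tuple[str, str], float] = {}
    for start in range(0, len(sources), family_size):
        family = [sources[i] for i in order[start:start + family_size]]
        bits = float(rng.uniform(100.0, 500.0))
        targets = [truth.mapping[u] for u in family]
        for u in family:
            for v in targets:
                entries[(u, v)] = bits
    return PairScoreTable(entries)


def make_fixtures(
    kind: str,
    params: dict | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
):
    """Generate a named fixture deterministically under ``seed``; when
    ``outdir`` is given the fixture is also written to disk."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if kind == "cycle":
        result = make_cycle(params.get("k", 6))
    elif kind == "path":
        result = make_path(params.get("k", 6))
    elif kind == "clique":
        result = make_clique(params.get("k", 5))
    elif kind == "er_random":
        result = make_er_random(params.get("n", 30), params.get("p", 0.15), rng)
    elif kind == "asymmetric_tree":
        result = make_asymmetric_tree(params.get("n", 12), rng)
    elif kind == "asymmetric_graph":
        result = make_asymmetric_graph(
            params.get("n", 30), params.get("p", 0.15), rng,
            distinct_gdv=params.get("distinct_gdv", False),
        )
    elif kind == "noisy_series":
        base = params.get("base")
        if base is None:
            base = make_asymmetric_graph(params.get("n", 30), params.get("p", 0.15), rng)
        result = make_noise_series(base, params.get("levels", DEFAULT_NOISE_LEVELS), rng=rng)
    elif kind == "annotations":
        result = make_annotations(
            params["truth"], params.get("share_rate", 0.7),
            params.get("n_terms", 20), params.get("experimental_rate", 0.5), rng,
        )
    elif kind == "seq_scores":
        result = make_seq_scores(params["truth"], params.get("family_size", 5), rng)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if out is not None:
        if isinstance(result, Network):
            write_network(result, out / f"{result.name}.el")
        elif isinstance(result, NoiseSeries):
            write_network(result.base, out / f"{result.base.name}.el")
            for x, net in result.variants.items():
                write_network(net, out / f"{result.base.name}_noise{x:g}.el")
            write_alignment(result.truth.mapping, out / f"{result.base.name}_truth.tsv")
        elif isinstance(result, AnnotationMap):
            write_annotations(result, out / "annotations.tsv")
        elif isinstance(result, PairScoreTable):
            write_pair_scores(result, out / "seq_scores.tsv")
    return result


# ---------------------------------------------------------------------------
# evaluation grid
# ---------------------------------------------------------------------------


@dataclass
class PairTask:
    """One network pair to align, with optional truth and side data.
    ``net1`` must be the smaller network."""

    name: str
    net1: Network
    net2: Network
    truth: TruthMapping | None = None
    seq_scores: PairScoreTable | None = None
    annotations: AnnotationMap | None = None

    def __post_init__(self) -> None:
        if self.net1.number_of_nodes() > self.net2.number_of_nodes():
            raise ValueError(f"pair {self.name!r}: net1 must be the smaller network")


@dataclass
class GridConfig:
    aligners: tuple[str, ...] = ALIGNERS
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID
    sizes: tuple[str, ...] = DEFAULT_SIZES
    bins: int = 32
    lam: float = 0.5
    topk: int | None = None


@dataclass
class GridResult:
    """Quality reports keyed by (pair name, aligner, alpha, size)."""

    cells: dict[tuple[str, str, float, str], QualityReport] = field(default_factory=dict)
    failures: dict[tuple[str, str, float, str], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pair, aligner, alpha, size), report in sorted(self.cells.items()):
            row = {"pair": pair, "aligner": aligner, "alpha": alpha, "size": size}
            row.update(report.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def all_pairs(networks: list[Network]) -> list[tuple[Network, Network]]:
    """All unordered pairs of distinct networks, smaller network first."""
    from .graph_io import smaller_first

    return [smaller_first(a, b) for a, b in itertools.combinations(networks, 2)]


def _topology_matrix(ncf: str, task: PairTask, size: str, bins: int) -> CostMatrix:
    if ncf == "M":
        return gdv_cost_matrix(task.net1, task.net2, size)
    return spectral_cost_matrix(task.net1, task.net2, HOP_LEVELS[size], bins)


def _within_matrices(ncf: str, task: PairTask, size: str, bins: int):
    if ncf == "M":
        return (
            gdv_cost_matrix(task.net1, task.net1, size),
            gdv_cost_matrix(task.net2, task.net2, size),
        )
    return (
        spectral_cost_matrix(task.net1, task.net1, HOP_LEVELS[size], bins),
        spectral_cost_matrix(task.net2, task.net2, HOP_LEVELS[size], bins),
    )


def run_cell(
    task: PairTask,
    aligner: str,
    alpha: float,
    size: str,
    config: GridConfig | None = None,
    _caches: dict | None = None,
) -> tuple[Alignment, QualityReport]:
    """Align one grid cell and score it."""
    config = config or GridConfig()
    caches = _caches if _caches is not None else {}
    ncf, strategy = aligner.split("-")

    key_t = ("T", task.name, ncf, size)
    if key_t not in caches:
        caches[key_t] = _topology_matrix(ncf, task, size, config.bins)
    Tmat = caches[key_t]
    key_s = ("S", task.name)
    if key_s not in caches:
        caches[key_s] = sequence_cost_matrix(task.seq_scores, task.net1.nodes, task.net2.nodes)
    Smat = caches[key_s]
    cost = blend(Tmat, Smat, alpha)
    if config.topk is not None:
        cost = topk_sparsify(cost, config.topk)

    if strategy == "M":
        alignment = align_seed_extend(task.net1, task.net2, cost)
    elif strategy == "G":
        key_w = ("W", task.name, ncf, size)
        if key_w not in caches:
            caches[key_w] = _within_matrices(ncf, task, size, config.bins)
        w1, w2 = caches[key_w]
        alignment = align_qap(task.net1, task.net2, cost, lam=config.lam,
                              within1=w1, within2=w2)
    else:
        raise ValueError(f"unknown alignment strategy letter {strategy!r}")
    alignment.aligner = aligner
    alignment.params.update({"alpha": alpha, "size": size})
    report = evaluate_alignment(task.net1, task.net2, alignment,
                                truth=task.truth, annotations=task.annotations)
    report.meta.update({"pair": task.name, "aligner": aligner,
                        "alpha": alpha, "size": size})
    return alignment, report


def run_grid(
    tasks: list[PairTask],
    config: GridConfig | None = None,
) -> GridResult:
    """Evaluate every (pair, aligner, alpha, size) cell; individual cell
    failures are recorded and the grid continues."""
    config = config or GridConfig()
    result = GridResult()
    caches: dict = {}
    for task in tasks:
        for aligner in config.aligners:
            for size in config.sizes:
                for alpha in config.alphas:
                    key = (task.name, aligner, alpha, size)
                    try:
                        _, report = run_cell(task, aligner, alpha, size, config, caches)
                        result.cells[key] = report
                    except Exception as exc:  # record, keep going
                        logger.warning("cell %s failed: %s", key, exc)
                        result.failures[key] = str(exc)
    return result


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _competition_ranks(scores: dict[str, float]) -> dict[str, int]:
    """Rank 1 = best (highest score); ties share the better rank."""
    return {
        a: 1 + sum(1 for other in scores.values() if other > s)
        for a, s in scores.items()
    }


def rank_aligners(grid: GridResult, scope: str = "all") -> pd.DataFrame:
    """Percentage of evaluation cases in which each aligner reached each
    rank.

    ``scope='all'`` ranks aligners within every (pair, alpha, size, measure)
    cell; ``scope='best'`` first maximizes each (pair, aligner, measure)
    over alpha and size, then ranks.  Returned frame: aligners x ranks,
    values are percentages of that aligner's ranked cases.
    """
    if scope not in ("all", "best"):
        raise ValueError(f"unknown scope {scope!r}")
    if not grid.cells:
        raise ValueError("empty grid")
    aligners = sorted({k[1] for k in grid.cells})
    counts = {a: {r: 0 for r in range(1, len(aligners) + 1)} for a in aligners}
    totals = {a: 0 for a in aligners}

    if scope == "all":
        universe: dict[tuple, dict[str, float]] = {}
        for (pair, aligner, alpha, size), report in grid.cells.items():
            for m in RANKED_MEASURES:
                v = getattr(report, m)
                if v is not None:
                    universe.setdefault((pair, alpha, size, m), {})[aligner] = v
    else:
        best: dict[tuple[str, str, str], float] = {}
        for (pair, aligner, alpha, size), report in grid.cells.items():
            for m in RANKED_MEASURES:
                v = getattr(report, m)
                if v is None:
                    continue
                key = (pair, m, aligner)
                if key not in best or v > best[key]:
                    best[key] = v
        universe = {}
        for (pair, m, aligner), v in best.items():
            universe.setdefault((pair, m), {})[aligner] = v

    for scores in universe.values():
        for a, r in _competition_ranks(scores).items():
            counts[a][r] += 1
            totals[a] += 1
    data = {
        a: [100.0 * counts[a][r] / totals[a] if totals[a] else np.nan
            for r in range(1, len(aligners) + 1)]
        for a in aligners
    }
    frame = pd.DataFrame(data, index=range(1, len(aligners) + 1)).T
    frame.index.name = "aligner"
    frame.columns.name = "rank"
    return frame


def correlation_analysis(
    grid: GridResult, select_by: str = "NC", method: str = "pearson"
) -> pd.DataFrame:
    """Correlate quality measures over the best alignments.

    For each (pair, aligner), the alignment with the highest ``select_by``
    score over alpha and size is selected; correlations are then computed
    across those reports.
    """
    if select_by not in RANKED_MEASURES:
        raise ValueError(f"cannot select by {select_by!r}")
    best: dict[tuple[str, str], QualityReport] = {}
    for (pair, aligner, alpha, size), report in grid.cells.items():
        v = getattr(report, select_by)
        if v is None:
            continue
        key = (pair, aligner)
        if key not in best or v > getattr(best[key], select_by):
            best[key] = report
    return measure_correlations(list(best.values()), method=method)
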