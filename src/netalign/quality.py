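"""Alignment quality measures.

Topological: node correctness (NC, needs a ground-truth mapping), edge
correctness (EC), induced conserved structure (ICS), symmetric substructure
score (S3), and the largest connected common subgraph (LCCS) score.  With
``E1`` the smaller network's edges and ``E2'`` the larger network's edges
between image nodes, and ``C`` the conserved edges (edges of E1 mapped onto
edges of E2):

* ``EC  = |C| / |E1| * 100``
* ``ICS = |C| / |E2'| * 100``
* ``S3  = |C| / (|E1| + |E2'| - |C|) * 100``
* ``LCCS = sqrt(N * E)`` where N is the percentage of V1 nodes in the
  largest connected component of the conserved-edge graph and E the
  percentage of its edges out of the minimum of the two induced edge counts
  on that component (and its image).

Biological: GO correctness (share of aligned pairs with a common GO term,
among pairs where both sides are annotated) and its experimental-evidence
variant EXP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .align import Alignment, TruthMapping
from .graph_io import AnnotationMap, Network

#: measures in report order
MEASURES = ("NC", "EC", "ICS", "S3", "LCCS_N", "LCCS_E", "LCCS", "GO", "EXP")


@dataclass
class QualityReport:
    """All scores of one alignment; unavailable measures stay ``None``."""

    NC: float | None = None
    EC: float = 0.0
    ICS: float = 0.0
    S3: float = 0.0
    LCCS_N: float = 0.0
    LCCS_E: float = 0.0
    LCCS: float = 0.0
    GO: float | None = None
    EXP: float | None = None
    conserved_edges: int = 0
    ics_defined: bool = True
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {m: getattr(self, m) for m in MEASURES}
        out["conserved_edges"] = self.conserved_edges
        out["ics_defined"] = self.ics_defined
        return out


def node_correctness(f: Alignment, h: TruthMapping) -> float:
    """Percentage of nodes whose aligned target agrees with the truth.

    Nodes for which the (possibly partial) truth is undefined are excluded
    from the denominator.
    """
    if not f.mapping:
        raise ValueError("empty alignment has no node correctness")
    scored = [u for u in f.mapping if u in h.mapping]
    if not scored:
        raise ValueError("truth mapping covers no aligned node")
    agree = sum(1 for u in scored if f.mapping[u] == h.mapping[u])
    return 100.0 * agree / len(scored)


def _conserved_graph(net1: Network, net2: Network, f: Alignment) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(f.mapping)
    for a, b in net1.edges:
        if net2.has_edge(f.mapping[a], f.mapping[b]):
            g.add_edge(a, b)
    return g


def topological_scores(
    net1: Network, net2: Network, f: Alignment
) -> tuple[float, float, float, float, float, float]:
    """Return (EC, ICS, S3, LCCS_N, LCCS_E, LCCS) for a total injective
    alignment of ``net1`` (smaller) into ``net2``."""
    if set(f.mapping) != set(net1.nodes):
        raise ValueError("alignment must be total on the smaller network")
    e1 = net1.number_of_edges()
    if e1 < 1:
        raise ValueError("smaller network has no edges")
    image = set(f.mapping.values())
    e2_prime = sum(1 for a, b in net2.edges if a in image and b in image)
    conserved_graph = _conserved_graph(net1, net2, f)
    conserved = conserved_graph.number_of_edges()

    ec = 100.0 * conserved / e1
    ics = 100.0 * conserved / e2_prime if e2_prime else 0.0
    s3 = 100.0 * conserved / (e1 + e2_prime - conserved)

    lccs_n = lccs_e = lccs = 0.0
    if conserved:
        components = sorted(
            nx.connected_components(conserved_graph),
            key=lambda c: (
                -len(c),
                -conserved_graph.subgraph(c).number_of_edges(),
                min(c),
            ),
        )
        lcc = components[0]
        lcc_edges = conserved_graph.subgraph(lcc).number_of_edges()
        induced1 = net1.subgraph(lcc).number_of_edges()
        induced2 = net2.subgraph({f.mapping[u] for u in lcc}).number_of_edges()
        alignable = min(induced1, induced2)
        lccs_n = 100.0 * len(lcc) / net1.number_of_nodes()
        lccs_e = 100.0 * lcc_edges / alignable if alignable else 0.0
        lccs = math.sqrt(lccs_n * lccs_e)
    return ec, ics, s3, lccs_n, lccs_e, lccs


def go_correctness(
    f: Alignment, ann: AnnotationMap, experimental_only: bool = False
) -> float | None:
    """Percentage of aligned pairs sharing at least one GO term, out of the
    aligned pairs in which both proteins are annotated.

    ``None`` (not 0) when no aligned pair has both sides annotated.  With
    ``experimental_only``, only experimentally evidenced annotations count.
    """
    if experimental_only:
        ann = ann.experimental_only()
    shared = total = 0
    for u, v in f.items():
        tu, tv = ann.terms(u), ann.terms(v)
        if tu and tv:
            total += 1
            if tu & tv:
                shared += 1
    if total == 0:
        return None
    return 100.0 * shared / total


def evaluate_alignment(
    net1: Network,
    net2: Network,
    f: Alignment,
    truth: TruthMapping | None = None,
    annotations: AnnotationMap | None = None,
) -> QualityReport:
    """Compute every applicable quality measure for one alignment."""
    ec, ics, s3, lccs_n, lccs_e, lccs = topological_scores(net1, net2, f)
    image = set(f.mapping.values())
    e2_prime = sum(1 for a, b in net2.edges if a in image and b in image)
    conserved = _conserved_graph(net1, net2, f).number_of_edges()
    report = QualityReport(
        EC=ec, ICS=ics, S3=s3,
        LCCS_N=lccs_n, LCCS_E=lccs_e, LCCS=lccs,
        conserved_edges=conserved,
        ics_defined=e2_prime > 0,
    )
    if truth is not None:
        report.NC = node_correctness(f, truth)
    if annotations is not None:
        report.GO = go_correctness(f, annotations, experimental_only=False)
        report.EXP = go_correctness(f, annotations, experimental_only=True)
    return report


def reports_frame(reports: list[QualityReport]) -> pd.DataFrame:
    """Stack reports into a DataFrame with one column per measure
    (undefined entries become NaN)."""
    rows = []
    for r in reports:
        rows.append({m: (np.nan if getattr(r, m) is None else getattr(r, m))
                     for m in MEASURES})
    return pd.DataFrame(rows, columns=list(MEASURES))


def measure_correlations(
    reports: list[QualityReport], method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlation between quality measures across alignments.

    ``method`` is ``pearson`` or ``spearman``; undefined scores are dropped
    pairwise; measures that never vary (or are never defined) come back as
    NaN rows/columns.  The diagonal is 1 for defined measures.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(reports) < 3:
        raise ValueError("need at least 3 reports to correlate measures")
    frame = reports_frame(reports)
    corr = frame.corr(method=method, min_periods=2)
    for m in MEASURES:
        col = frame[m].dropna()
        if len(col) >= 2 and col.nunique() > 1:
            corr.loc[m, m] = 1.0
        else:
            corr.loc[m, :] = np.nan
            corr.loc[:, m] = np.nan
    return corr
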