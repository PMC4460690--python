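"""Spectral node cost function.

A node's topological signature is the multi-radius spectrum of its k-hop
neighborhoods: for each radius r = 1..k, take the induced subgraph on all
nodes within shortest-path distance r of the node (center included),
compute the eigenvalues of its normalized Laplacian
``L = I - D^(-1/2) A D^(-1/2)`` (all in [0, 2]; an isolated vertex
contributes eigenvalue 0) and bin them into B equal-width bins over [0, 2],
normalized to unit mass.  Two signatures are compared by the mean over
levels of half the L1 distance between the level histograms, a metric in
[0, 1]; similarity is its complement.

The k-hop levels k = 1..4 play the role of neighborhood sizes T1-T4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse.linalg
import scipy.spatial.distance

from .graph_io import Network
from .ncf_blend import CostMatrix

logger = logging.getLogger(__name__)

DEFAULT_BINS = 32

#: above this ball size only the extreme ends of the spectrum are computed
DENSE_EIG_LIMIT = 500

#: neighborhood-size level -> k-hop radius
HOP_LEVELS: dict[str, int] = {"T1": 1, "T2": 2, "T3": 3, "T4": 4}


@dataclass(frozen=True)
class SpectralSignature:
    """Per-level eigenvalue histograms of a node's r-ball Laplacians."""

    node: str
    k: int
    bins: int
    histograms: np.ndarray  # (k, bins); each row sums to 1

    def __post_init__(self) -> None:
        if self.histograms.shape != (self.k, self.bins):
            raise ValueError("histogram shape does not match (k, bins)")


def khop_ball(net: Network, node: str, r: int) -> Network:
    """Induced subgraph on the closed r-ball around ``node``."""
    if node not in net:
        raise ValueError(f"node {node!r} not in network {net.name!r}")
    if r < 1:
        raise ValueError(f"radius must be >= 1, got {r}")
    dist = nx.single_source_shortest_path_length(net.graph, node, cutoff=r)
    return net.subgraph(dist.keys(), name=f"{net.name}|ball({node},{r})")


def _ball_spectrum(g: nx.Graph) -> np.ndarray:
    n = g.number_of_nodes()
    if n == 1:
        return np.zeros(1)
    nodelist = sorted(g.nodes)
    L = nx.normalized_laplacian_matrix(g, nodelist=nodelist)
    if n <= DENSE_EIG_LIMIT:
        return np.linalg.eigvalsh(L.toarray())
    logger.warning(
        "ball with %d nodes exceeds dense limit; binning a truncated spectrum", n
    )
    half = DENSE_EIG_LIMIT // 2
    lo = scipy.sparse.linalg.eigsh(L.asfptype(), k=half, which="SA",
                                   return_eigenvectors=False)
    hi = scipy.sparse.linalg.eigsh(L.asfptype(), k=half, which="LA",
                                   return_eigenvectors=False)
    return np.concatenate([lo, hi])


def _bin_spectrum(eigs: np.ndarray, bins: int) -> np.ndarray:
    # snap to 9 decimals so eigenvalues mathematically on a bin edge (e.g. 1.0)
    # bin identically regardless of node ordering, then clip numerical slack
    eigs = np.clip(np.round(eigs, 9), 0.0, 2.0)
    hist, _ = np.histogram(eigs, bins=bins, range=(0.0, 2.0))
    return hist / hist.sum()


def spectral_signature(
    net: Network, node: str, k: int = 4, bins: int = DEFAULT_BINS
) -> SpectralSignature:
    """Spectral signature of ``node``: binned r-ball spectra for r = 1..k."""
    if k not in (1, 2, 3, 4):
        raise ValueError(f"k must be in 1..4, got {k}")
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    if node not in net:
        raise ValueError(f"node {node!r} not in network {net.name!r}")
    dist = nx.single_source_shortest_path_length(net.graph, node, cutoff=k)
    histograms = np.empty((k, bins))
    for r in range(1, k + 1):
        members = [v for v, d in dist.items() if d <= r]
        ball = net.graph.subgraph(members)
        histograms[r - 1] = _bin_spectrum(_ball_spectrum(ball), bins)
    return SpectralSignature(node=node, k=k, bins=bins, histograms=histograms)


def spectral_distance(sig1: SpectralSignature, sig2: SpectralSignature) -> float:
    """Mean over levels of half the L1 distance between level histograms.

    A metric in [0, 1]; 0 iff the histograms are identical.
    """
    if sig1.k != sig2.k or sig1.bins != sig2.bins:
        raise ValueError("signatures have mismatched k or bin count")
    per_level = 0.5 * np.abs(sig1.histograms - sig2.histograms).sum(axis=1)
    return float(per_level.mean())


def _signature_stack(net: Network, k: int, bins: int) -> np.ndarray:
    sigs = np.empty((net.number_of_nodes(), k * bins))
    for i, node in enumerate(net.nodes):
        sigs[i] = spectral_signature(net, node, k, bins).histograms.ravel()
    return sigs


def spectral_cost_matrix(
    net1: Network, net2: Network, k: int = 4, bins: int = DEFAULT_BINS
) -> CostMatrix:
    """Full |V1| x |V2| spectral similarity matrix (1 - distance)."""
    if net1.number_of_nodes() > net2.number_of_nodes():
        raise ValueError("net1 must be the smaller network")
    s1 = _signature_stack(net1, k, bins)
    s2 = _signature_stack(net2, k, bins) if net2 is not net1 else s1
    d = scipy.spatial.distance.cdist(s1, s2, metric="cityblock") * (0.5 / k)
    return CostMatrix(rows=net1.nodes, cols=net2.nodes,
                      values=np.clip(1.0 - d, 0.0, 1.0), provenance="topology")
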