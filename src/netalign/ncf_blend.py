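"""Normalization, completion, blending and sparsification of node-score
matrices into the final node cost function consumed by alignment strategies.

Topological similarities T and sequence similarities S (both scaled to
[0, 1]) are mixed as ``alpha*T + (1-alpha)*S``; alpha = 1 is topology only,
alpha = 0 sequence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph_io import PairScoreTable

#: the alpha grid used by parameter sweeps (11 values, step 0.1)
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

#: default alpha for a single run
DEFAULT_ALPHA = 0.5

_EPS = 1e-9


@dataclass
class CostMatrix:
    """|V1| x |V2| node-similarity scores in [0, 1].

    Rows follow the node order of the smaller network, columns of the
    larger.  ``provenance`` records whether the scores are topological,
    sequence-derived, or an alpha-blend.
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: np.ndarray
    provenance: str = "topology"
    _row_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _col_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rows = tuple(self.rows)
        self.cols = tuple(self.cols)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.rows)} x {len(self.cols)} labels"
            )
        if self.values.size and (
            self.values.min() < -_EPS or self.values.max() > 1.0 + _EPS
        ):
            raise ValueError("cost matrix values must lie in [0, 1]")
        self._row_index = {lab: i for i, lab in enumerate(self.rows)}
        self._col_index = {lab: j for j, lab in enumerate(self.cols)}

    def get(self, row: str, col: str) -> float:
        return float(self.values[self._row_index[row], self._col_index[col]])

    def row_of(self, label: str) -> int:
        return self._row_index[label]

    def col_of(self, label: str) -> int:
        return self._col_index[label]

    def to_table(self) -> PairScoreTable:
        """Sparse TSV-roundtrippable view (zero entries dropped)."""
        entries = {
            (a, b): float(self.values[i, j])
            for i, a in enumerate(self.rows)
            for j, b in enumerate(self.cols)
            if self.values[i, j] != 0.0
        }
        return PairScoreTable(entries)


def normalize_similarities(
    raw: np.ndarray,
    rows: Sequence[str],
    cols: Sequence[str],
    provenance: str = "topology",
) -> CostMatrix:
    """Scale non-negative raw scores to [0, 1] by dividing by the global
    maximum (so the best pair scores exactly 1)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty score matrix")
    if raw.min() < 0:
        raise ValueError("raw similarity scores must be non-negative")
    top = raw.max()
    if top == 0:
        raise ValueError("all-zero score matrix cannot be normalized")
    return CostMatrix(tuple(rows), tuple(cols), raw / top, provenance)


def distances_to_similarities(dist: CostMatrix) -> CostMatrix:
    """Convert a distance matrix in [0, 1] to similarities as ``1 - d``.

    Applying the conversion twice returns the input (involution).
    """
    return CostMatrix(dist.rows, dist.cols, 1.0 - dist.values, dist.provenance)


def complete_partial_distances(
    partial: PairScoreTable,
    rows: Sequence[str],
    cols: Sequence[str],
) -> np.ndarray:
    """Fill a partial distance table to a full |rows| x |cols| matrix.

    Pairs without a reported distance get the highest observed distance
    (i.e. they are treated as maximally dissimilar).
    """
    if not partial.entries:
        raise ValueError("cannot complete an empty distance table")
    fill = partial.max_score()
    mat = np.full((len(rows), len(cols)), fill, dtype=float)
    row_index = {lab: i for i, lab in enumerate(rows)}
    col_index = {lab: j for j, lab in enumerate(cols)}
    for (a, b), d in partial.entries.items():
        if a in row_index and b in col_index:
            mat[row_index[a], col_index[b]] = d
    return mat


def sequence_cost_matrix(
    scores: PairScoreTable | None,
    rows: Sequence[str],
    cols: Sequence[str],
) -> CostMatrix:
    """Build the sequence-similarity matrix S from raw pair scores (e.g.
    BLAST bit scores): divide by the global maximum over observed
    cross-network pairs; pairs with no reported score get 0."""
    mat = np.zeros((len(rows), len(cols)), dtype=float)
    if scores is not None and scores.entries:
        row_index = {lab: i for i, lab in enumerate(rows)}
        col_index = {lab: j for j, lab in enumerate(cols)}
        top = max(
            (s for (a, b), s in scores.entries.items()
             if a in row_index and b in col_index),
            default=0.0,
        )
        if top > 0:
            for (a, b), s in scores.entries.items():
                if a in row_index and b in col_index:
                    mat[row_index[a], col_index[b]] = s / top
    return CostMatrix(tuple(rows), tuple(cols), mat, provenance="sequence")


def blend(Tmat: CostMatrix, Smat: CostMatrix, alpha: float) -> CostMatrix:
    """Mix topology and sequence similarities as ``alpha*T + (1-alpha)*S``.

    alpha = 1 returns T exactly; alpha = 0 returns S exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if Tmat.values.shape != Smat.values.shape:
        raise ValueError("T and S matrices have different shapes")
    if Tmat.rows != Smat.rows or Tmat.cols != Smat.cols:
        raise ValueError("T and S matrices index different node sets")
    if alpha == 1.0:
        values = Tmat.values.copy()
    elif alpha == 0.0:
        values = Smat.values.copy()
    else:
        values = alpha * Tmat.values + (1.0 - alpha) * Smat.values
    return CostMatrix(Tmat.rows, Tmat.cols, values, provenance="blended")


def topk_sparsify(mat: CostMatrix, K: int) -> CostMatrix:
    """Keep only the K largest entries, zeroing the rest.

    Ties at the K-th value are broken by (row, col) lexicographic position,
    so the output is deterministic.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    n = mat.values.size
    if K >= n:
        return CostMatrix(mat.rows, mat.cols, mat.values.copy(), mat.provenance)
    flat = mat.values.ravel()
    # sort by descending value, then ascending flat (row-major) position
    order = np.lexsort((np.arange(n), -flat))
    keep = order[:K]
    out = np.zeros(n)
    out[keep] = flat[keep]
    return CostMatrix(mat.rows, mat.cols, out.reshape(mat.values.shape), mat.provenance)
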