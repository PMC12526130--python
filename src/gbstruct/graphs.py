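"""Spatial neighbor graphs and per-cell neighborhood composition.

Two graph flavors are used downstream: a fixed-radius graph (default
40 µm) feeding neighborhood enrichment, and a k-nearest-neighbor graph
(default k=15, symmetrized) feeding niche composition and refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import CellMap, ValidationError

__all__ = [
    "SpatialGraph",
    "build_radius_graph",
    "build_knn_graph",
    "neighborhood_composition",
    "CompositionMatrix",
]


@dataclass(frozen=True)
class SpatialGraph:
    """Symmetric cell–cell adjacency over one CellMap.

    Edges are stored once as index pairs ``(edges_i[k], edges_j[k])`` with
    ``edges_i < edges_j`` into the cell map's row order. No self-loops.
    """

    cell_ids: np.ndarray
    edges_i: np.ndarray
    edges_j: np.ndarray
    flavor: str  # "radius" | "knn"
    parameter: float

    def __post_init__(self) -> None:
        if len(self.edges_i) != len(self.edges_j):
            raise ValidationError("edge index arrays must have equal length")
        if len(self.edges_i) and (self.edges_i >= self.edges_j).any():
            raise ValidationError("edges must be stored with i < j")
        n = len(self.cell_ids)
        if len(self.edges_j) and self.edges_j.max() >= n:
            raise ValidationError("edge endpoint outside the cell list")

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges_i)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges_i, 1)
        np.add.at(deg, self.edges_j, 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency lists (row indices), for small-graph consumers."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in zip(self.edges_i, self.edges_j):
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(v), dtype=np.int64) for v in nbrs]


def _check_cellmap(cells: CellMap) -> np.ndarray:
    xy = cells.coords
    if not np.all(np.isfinite(xy)):
        raise ValidationError("non-finite coordinate in cell map")
    return xy


def build_radius_graph(cells: CellMap, radius: float) -> SpatialGraph:
    """Connect every pair of cells at Euclidean distance in (0, radius].

    The boundary is inclusive: two cells exactly ``radius`` apart are
    linked. Coincident cells (distance 0) are not linked to themselves but
    distinct cells at distance 0 are.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    xy = _check_cellmap(cells)
    pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        i = np.minimum(pairs[:, 0], pairs[:, 1])
        j = np.maximum(pairs[:, 0], pairs[:, 1])
        order = np.lexsort((j, i))
        i, j = i[order], j[order]
    else:
        i = j = np.empty(0, dtype=np.int64)
    return SpatialGraph(cells.cell_ids, i, j, "radius", float(radius))


def build_knn_graph(cells: CellMap, k: int) -> SpatialGraph:
    """Link each cell to its k nearest neighbors, symmetrized by union.

    Distance ties at the kth neighbor are broken toward the smaller
    ``cell_id`` (string order), so the graph is reproducible on gridded
    coordinates. Every node's out-degree before symmetrization is exactly
    k; the union symmetrization can only add edges.
    """
    n = cells.n_cells
    if not (1 <= k < n):
        raise ValidationError(f"k must satisfy 1 <= k < n_cells, got k={k}, n={n}")
    xy = _check_cellmap(cells)
    # query k+1 then strip self; resolve distance ties by cell_id rank
    dist, idx = cKDTree(xy).query(xy, k=min(k + 2, n))
    id_rank = np.argsort(np.argsort(cells.cell_ids.astype(str)))
    rows = []
    for i in range(n):
        cand_idx = idx[i][idx[i] != i]
        cand_dist = dist[i][idx[i] != i]
        if len(cand_idx) > k and cand_dist[k - 1] == cand_dist[k]:
            # tie at the boundary: reorder candidates at the tied distance
            tie_val = cand_dist[k - 1]
            tied = cand_idx[cand_dist == tie_val]
            tied = tied[np.argsort(id_rank[tied])]
            keep = cand_idx[cand_dist < tie_val]
            take = k - len(keep)
            chosen = np.concatenate([keep, tied[:take]])
        else:
            chosen = cand_idx[:k]
        # kd-tree may truncate under coincident points; re-query widely
        if len(chosen) < k:
            d_all = np.hypot(*(xy - xy[i]).T)
            order = np.lexsort((id_rank, d_all))
            order = order[order != i]
            chosen = order[:k]
        rows.append(chosen)
    src = np.repeat(np.arange(n), k)
    dst = np.concatenate(rows)
    i = np.minimum(src, dst)
    j = np.maximum(src, dst)
    uniq = np.unique(np.stack([i, j], axis=1), axis=0)
    return SpatialGraph(cells.cell_ids, uniq[:, 0], uniq[:, 1], "knn", float(k))


@dataclass(frozen=True)
class CompositionMatrix:
    """Per-cell neighbor cell-type proportions.

    ``values`` is cells × cell-types; non-isolated rows sum to 1, isolated
    cells (no neighbors) carry an all-zero row and are flagged.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    cell_types: tuple[str, ...]
    isolated: np.ndarray  # boolean mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=list(self.cell_types)
        )


def neighborhood_composition(
    cells: CellMap, graph: SpatialGraph
) -> CompositionMatrix:
    """Row i = type frequencies among i's graph neighbors (focal excluded)."""
    if graph.n_nodes != cells.n_cells or not np.array_equal(
        graph.cell_ids, cells.cell_ids
    ):
        raise ValidationError("graph was not built on this cell map")
    types = tuple(cells.label_set)
    t_index = {t: c for c, t in enumerate(types)}
    codes = np.array([t_index[t] for t in cells.cell_types])
    counts = np.zeros((cells.n_cells, len(types)), dtype=np.float64)
    np.add.at(counts, (graph.edges_i, codes[graph.edges_j]), 1.0)
    np.add.at(counts, (graph.edges_j, codes[graph.edges_i]), 1.0)
    deg = counts.sum(axis=1)
    isolated = deg == 0
    values = np.divide(
        counts, deg[:, None], out=np.zeros_like(counts), where=deg[:, None] > 0
    )
    return CompositionMatrix(values, cells.cell_ids, types, isolated)
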