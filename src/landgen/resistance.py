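"""Landscape distance matrices: geographic, environmental, least-cost, commute.

The habitat-probability raster acts as a conductance surface: each cell's
conductance equals its habitat value, the conductance of an edge between
adjacent cells is the (arithmetic, by default) mean of the two cell
conductances, and the traversal cost of the edge is the inter-center
distance divided by the edge conductance. Least-cost distances are exact
shortest paths on that graph; commute distances are circuit-theoretic
effective resistances computed from the graph Laplacian built on edge
conductances (1 / edge cost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import splu
from scipy.spatial.distance import pdist, squareform

from .raster import RasterLayer

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseMatrix",
    "TransitionGraph",
    "build_transition",
    "least_cost_matrix",
    "accumulated_cost_surface",
    "commute_matrix",
    "geographic_distance_matrix",
    "environmental_distance_matrix",
]

#: kinds whose entries may legitimately dip below zero (Weir-Cockerham theta)
_SIGNED_KINDS = {"genetic"}


@dataclass
class PairwiseMatrix:
    """Symmetric location x location distance matrix with a kind tag."""

    values: pd.DataFrame
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(np.asarray(v, dtype=float))
            self.values = v
        arr = v.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("pairwise matrix must be square")
        finite = np.isfinite(arr)
        if not np.allclose(arr[finite.T & finite], arr.T[finite.T & finite],
                           atol=1e-8):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-8):
            raise ValueError("pairwise matrix must have a zero diagonal")
        if self.kind not in _SIGNED_KINDS and np.any(arr[finite] < -1e-12):
            raise ValueError(f"negative entries not allowed for kind={self.kind!r}")

    @property
    def ids(self) -> list:
        return list(self.values.index)

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.array, checks=False)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "PairwiseMatrix":
        return cls(pd.read_csv(path, index_col=0), kind=kind)

    @classmethod
    def from_array(cls, arr, ids=None, kind: str = "generic") -> "PairwiseMatrix":
        arr = np.asarray(arr, dtype=float)
        if ids is None:
            ids = list(range(arr.shape[0]))
        return cls(pd.DataFrame(arr, index=ids, columns=ids), kind=kind)


@dataclass
class TransitionGraph:
    """Weighted graph over the passable cells of a conductance raster."""

    raster: RasterLayer
    costs: sparse.csr_matrix        # edge traversal costs, symmetric
    node_of_cell: np.ndarray        # (rows, cols) int, -1 for impassable
    cells_of_node: np.ndarray       # (n_nodes, 2) row/col per node
    neighbors: int = 8
    mean_rule: str = "arithmetic"
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.costs.shape[0]

    def node_at(self, row: int, col: int) -> int:
        node = int(self.node_of_cell[row, col])
        if node < 0:
            raise ValueError(f"cell ({row}, {col}) is impassable (nodata or zero habitat)")
        return node

    def nodes_at_points(self, x, y) -> np.ndarray:
        rows, cols = self.raster.rowcol_from_xy(x, y)
        return np.array([self.node_at(r, c) for r, c in
                         zip(np.atleast_1d(rows), np.atleast_1d(cols))])


def build_transition(habitat: RasterLayer, neighbors: int = 8,
                     mean_rule: str = "arithmetic") -> TransitionGraph:
    """Build the cost graph from a habitat/conductance raster.

    Cells with nodata or zero conductance have no edges (impassable).
    Edge cost = inter-center distance (1 rook / sqrt(2) diagonal, in cell
    units) divided by the mean of the two cell conductances.
    """
    if neighbors not in (4, 8):
        raise ValueError("neighbors must be 4 or 8")
    if mean_rule not in ("arithmetic", "geometric"):
        raise ValueError("mean_rule must be 'arithmetic' or 'geometric'")
    cond = np.asarray(habitat.values, dtype=float)
    if np.nanmin(cond[np.isfinite(cond)]) < 0 or np.nanmax(cond[np.isfinite(cond)]) > 1:
        raise ValueError("habitat conductance values must lie in [0, 1]")
    passable = np.isfinite(cond) & (cond > 0)
    if not passable.any():
        raise ValueError("raster is fully impassable")
    nrows, ncols = cond.shape
    node_of_cell = -np.ones((nrows, ncols), dtype=int)
    cells = np.argwhere(passable)
    node_of_cell[cells[:, 0], cells[:, 1]] = np.arange(len(cells))

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbors == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]

    rows_i, rows_j, costs = [], [], []
    for dr, dc, dist in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a = node_of_cell[r0, c0].ravel()
        b = node_of_cell[r1, c1].ravel()
        ca = cond[r0, c0].ravel()
        cb = cond[r1, c1].ravel()
        ok = (a >= 0) & (b >= 0)
        if mean_rule == "arithmetic":
            ec = 0.5 * (ca[ok] + cb[ok])
        else:
            ec = np.sqrt(ca[ok] * cb[ok])
        rows_i.append(a[ok])
        rows_j.append(b[ok])
        costs.append(dist / ec)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(costs)
    n = len(cells)
    m = sparse.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    return TransitionGraph(habitat, m.tocsr(), node_of_cell, cells,
                           neighbors=neighbors, mean_rule=mean_rule)


def _location_nodes(graph: TransitionGraph, locations: pd.DataFrame) -> np.ndarray:
    if {"row", "col"}.issubset(locations.columns):
        return np.array([graph.node_at(int(r), int(c))
                         for r, c in zip(locations["row"], locations["col"])])
    return graph.nodes_at_points(locations["x"].to_numpy(),
                                 locations["y"].to_numpy())


def least_cost_matrix(graph: TransitionGraph,
                      locations: pd.DataFrame) -> PairwiseMatrix:
    """Exact shortest-path cost between every pair of locations.

    ``locations`` needs either row/col or x/y columns plus a ``pop_id``
    column (falls back to the frame index). Disconnected pairs come back
    infinite and are logged.
    """
    nodes = _location_nodes(graph, locations)
    dist = dijkstra(graph.costs, directed=False, indices=nodes)
    d = dist[:, nodes]
    d = 0.5 * (d + d.T)  # symmetric up to float noise
    np.fill_diagonal(d, 0.0)
    n_inf = int(np.isinf(d).sum() // 2)
    if n_inf:
        logger.warning("least_cost_matrix: %d location pairs are disconnected", n_inf)
    ids = list(locations["pop_id"]) if "pop_id" in locations.columns else list(locations.index)
    return PairwiseMatrix.from_array(d, ids=ids, kind="least_cost")


def accumulated_cost_surface(graph: TransitionGraph, origin) -> RasterLayer:
    """Least-cost distance from one origin to every passable cell.

    ``origin`` is a (row, col) pair or a node index. Impassable and
    unreachable cells are nodata.
    """
    node = graph.node_at(*origin) if np.iterable(origin) else int(origin)
    dist = dijkstra(graph.costs, directed=False, indices=node)
    out = np.full(graph.raster.shape, np.nan)
    out[graph.cells_of_node[:, 0], graph.cells_of_node[:, 1]] = dist
    out[np.isinf(out)] = np.nan
    return graph.raster.copy_with(out, name="accumulated_cost")


def commute_matrix(graph: TransitionGraph,
                   locations: pd.DataFrame) -> PairwiseMatrix:
    """Circuit-theoretic effective-resistance distance between locations.

    The graph Laplacian is built on edge conductances (reciprocal edge
    costs); the effective resistance between two locations is obtained by
    grounding one node and solving the reduced sparse system. Pairs in
    different components are infinite and logged.
    """
    nodes = _location_nodes(graph, locations)
    conduct = graph.costs.copy()
    conduct.data = 1.0 / conduct.data
    n = conduct.shape[0]
    deg = np.asarray(conduct.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - conduct
    # identify components so cross-component pairs are reported, not crashed
    n_comp, comp = sparse.csgraph.connected_components(graph.costs, directed=False)
    k = len(nodes)
    out = np.full((k, k), np.inf)
    np.fill_diagonal(out, 0.0)
    for c in np.unique(comp[nodes]):
        members = np.flatnonzero(comp == c)
        sel = [i for i in range(k) if comp[nodes[i]] == c]
        if len(sel) < 2:
            continue
        sub = lap[members][:, members].tocsc()
        # ground the last node of the component
        red = sub[:-1, :-1].tocsc()
        lu = splu(red.tocsc() + sparse.eye(red.shape[0], format="csc") * 1e-12)
        pos = {g: i for i, g in enumerate(members)}
        vcols = {}
        for i in sel:
            p = pos[nodes[i]]
            e = np.zeros(red.shape[0])
            if p < red.shape[0]:
                e[p] = 1.0
            vcols[i] = lu.solve(e)
        for ai in range(len(sel)):
            for bi in range(ai + 1, len(sel)):
                i, j = sel[ai], sel[bi]
                pi, pj = pos[nodes[i]], pos[nodes[j]]
                vi, vj = vcols[i], vcols[j]
                gii = vi[pi] if pi < red.shape[0] else 0.0
                gjj = vj[pj] if pj < red.shape[0] else 0.0
                gij = vi[pj] if pj < red.shape[0] else 0.0
                gji = vj[pi] if pi < red.shape[0] else 0.0
                out[i, j] = out[j, i] = gii + gjj - gij - gji
    n_inf = int(np.isinf(out).sum() // 2)
    if n_inf:
        logger.warning("commute_matrix: %d location pairs are disconnected", n_inf)
    ids = list(locations["pop_id"]) if "pop_id" in locations.columns else list(locations.index)
    return PairwiseMatrix.from_array(np.maximum(out, 0.0), ids=ids, kind="commute")


def geographic_distance_matrix(coords: pd.DataFrame) -> PairwiseMatrix:
    """Pairwise Euclidean distance between projected coordinates (x, y)."""
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    d = squareform(pdist(xy))
    ids = list(coords["pop_id"]) if "pop_id" in coords.columns else list(coords.index)
    return PairwiseMatrix.from_array(d, ids=ids, kind="geographic")


def environmental_distance_matrix(env: pd.DataFrame,
                                  standardize: bool = True) -> PairwiseMatrix:
    """Pairwise Euclidean distance on (standardized) environmental values."""
    x = env.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite environmental values")
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x))
    return PairwiseMatrix.from_array(d, ids=list(env.index), kind="environmental")
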