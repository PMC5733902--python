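"""Conductance surfaces, lattice graphs, commute-time resistance distances,
matrix normalization and collinearity (VIF).

A conductance raster defines an undirected weighted grid graph (4- or
8-neighbor). The commute time between two nodes of a connected component is

    C(i, j) = vol(G) * R_eff(i, j)

with vol(G) twice the sum of edge weights of the component and R_eff the
effective resistance from the weighted Laplacian pseudo-inverse.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from ._util import pairwise_haversine_km, validate_coords
from .io_formats import Raster

#: floor of the min-max rescaled conductance; keeps every edge weight > 0
CONDUCTANCE_EPS = 1e-3


@dataclasses.dataclass(frozen=True)
class Scenario:
    """A resistance hypothesis: which raster drives it and in which direction.

    `high_is_conductive` is True when high raster values mean easy movement.
    """

    name: str
    raster_role: str
    high_is_conductive: bool


SCENARIOS: dict[str, Scenario] = {
    # warm areas are easy to cross; cold (low minimum temperature) resists
    "T": Scenario("T", "temperature", True),
    # high elevation resists
    "E": Scenario("E", "elevation", False),
    # dense pine as resistance (philopatry in rich habitat)
    "Pr": Scenario("Pr", "pine_density", False),
    # dense pine as corridor
    "Pc": Scenario("Pc", "pine_density", True),
}


def scenario_conductance(raster: Raster, scenario: Scenario,
                         eps: float = CONDUCTANCE_EPS) -> Raster:
    """Min-max rescale the raster to [eps, 1]; flip when high raster values
    mean low conductance. Output values are strictly positive."""
    vals = raster.data
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("raster needs >= 2 valid cells")
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        raise ValueError("constant raster has no contrast")
    scaled = eps + (1.0 - eps) * (vals - lo) / (hi - lo)
    if not scenario.high_is_conductive:
        scaled = (1.0 + eps) - scaled
    out = np.where(finite, scaled, np.nan)
    return Raster(out, raster.xllcorner, raster.yllcorner, raster.cellsize,
                  nodata=raster.nodata, units="conductance")


@dataclasses.dataclass
class ConductanceGraph:
    """Grid graph over the valid cells of a conductance raster."""

    raster: Raster
    connectivity: int
    node_of_cell: np.ndarray      # (rows, cols) int; -1 for NoData cells
    cell_of_node: np.ndarray      # (n_nodes, 2) row/col per node
    edges: np.ndarray             # (n_edges, 2) node index pairs
    weights: np.ndarray           # (n_edges,) positive conductances
    component: np.ndarray         # (n_nodes,) component label

    @property
    def n_nodes(self) -> int:
        return self.cell_of_node.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_nodes
        return coo_matrix(
            (np.concatenate([self.weights, self.weights]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n)).tocsr()


def build_graph(conductance: Raster, connectivity: int = 8) -> ConductanceGraph:
    """Lattice graph over valid cells. Edge weight is the mean of the two
    cells' conductances; diagonal edges are additionally divided by sqrt(2)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    vals = conductance.data
    valid = np.isfinite(vals)
    if not valid.any():
        raise ValueError("raster has no valid cells")
    if np.any(vals[valid] <= 0):
        raise ValueError("conductance values must be positive")
    rows, cols = vals.shape
    node_of_cell = np.full((rows, cols), -1, dtype=np.int64)
    rr, cc = np.nonzero(valid)
    node_of_cell[rr, cc] = np.arange(rr.size)
    cell_of_node = np.column_stack([rr, cc])

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, 1.0 / np.sqrt(2.0)), (1, -1, 1.0 / np.sqrt(2.0))]
    edge_i, edge_j, edge_w = [], [], []
    for dr, dc, factor in offsets:
        # cell (r, c) pairs with (r + dr, c + dc); dr in {0, 1}, dc in {-1, 0, 1}
        sa = (slice(0, rows - dr), slice(max(0, -dc), cols - max(0, dc)))
        sb = (slice(dr, rows), slice(max(0, dc), cols - max(0, -dc)))
        a, b = node_of_cell[sa], node_of_cell[sb]
        va, vb = vals[sa], vals[sb]
        ok = (a >= 0) & (b >= 0)
        edge_i.append(a[ok])
        edge_j.append(b[ok])
        edge_w.append(factor * 0.5 * (va[ok] + vb[ok]))
    edges = np.column_stack([np.concatenate(edge_i), np.concatenate(edge_j)])
    weights = np.concatenate(edge_w)
    n = cell_of_node.shape[0]
    adj = coo_matrix((weights, (edges[:, 0], edges[:, 1])), shape=(n, n))
    _, labels = connected_components(adj + adj.T, directed=False)
    return ConductanceGraph(conductance, connectivity, node_of_cell,
                            cell_of_node, edges, weights, labels)


def graph_from_edges(n_nodes: int, edges: Sequence[tuple[int, int]],
                     weights: Sequence[float]) -> ConductanceGraph:
    """Build a ConductanceGraph from an explicit edge list (no raster
    geometry); handy for oracles and non-lattice graphs."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("edge weights must be positive")
    dummy = Raster(np.ones((1, max(n_nodes, 1))), 0.0, 0.0, 1.0)
    node_of_cell = np.arange(n_nodes, dtype=np.int64).reshape(1, -1)
    cell_of_node = np.column_stack([np.zeros(n_nodes, dtype=np.int64),
                                    np.arange(n_nodes, dtype=np.int64)])
    adj = coo_matrix((weights, (edges[:, 0], edges[:, 1])),
                     shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj + adj.T, directed=False)
    return ConductanceGraph(dummy, 4, node_of_cell, cell_of_node, edges,
                            weights, labels)


def snap_to_node(graph: ConductanceGraph, lon: float, lat: float) -> int:
    """Node index of the cell containing (lon, lat); if that cell is NoData,
    snap to the nearest valid cell within 1 cell, else raise."""
    raster = graph.raster
    row, col = raster.index_of(lon, lat)
    rows, cols = raster.data.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"point ({lon}, {lat}) outside raster extent")
    if graph.node_of_cell[row, col] >= 0:
        return int(graph.node_of_cell[row, col])
    best = -1
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r, c = row + dr, col + dc
            if 0 <= r < rows and 0 <= c < cols and graph.node_of_cell[r, c] >= 0:
                best = int(graph.node_of_cell[r, c])
                break
        if best >= 0:
            break
    if best < 0:
        raise ValueError(f"point ({lon}, {lat}) falls on NoData with no valid "
                         "cell within 1 cell")
    return best


def commute_distance(graph: ConductanceGraph,
                     nodes: Sequence[int] | None = None,
                     lonlats: Sequence[tuple[float, float]] | None = None
                     ) -> np.ndarray:
    """Pairwise commute times between the given nodes (or lon/lat points).

    Exact per connected component via a grounded-Laplacian sparse solve;
    pairs in different components get +inf.
    """
    if nodes is None:
        if lonlats is None:
            raise ValueError("provide nodes or lonlats")
        nodes = [snap_to_node(graph, lon, lat) for lon, lat in lonlats]
    nodes = np.asarray(nodes, dtype=np.int64)
    m = nodes.size
    out = np.full((m, m), np.inf)
    np.fill_diagonal(out, 0.0)
    comp = graph.component[nodes]
    for label in np.unique(comp):
        sel = np.nonzero(comp == label)[0]
        if sel.size < 2:
            continue
        member_nodes = np.nonzero(graph.component == label)[0]
        sub = _effective_resistance(graph, member_nodes, nodes[sel])
        in_comp = np.isin(graph.edges[:, 0], member_nodes)
        vol = 2.0 * graph.weights[in_comp].sum()
        out[np.ix_(sel, sel)] = vol * sub
        out[sel, sel] = 0.0
    return out


def _effective_resistance(graph: ConductanceGraph, member_nodes: np.ndarray,
                          query_nodes: np.ndarray) -> np.ndarray:
    """Effective resistances between `query_nodes` inside one component."""
    # relabel component nodes 0..k-1
    remap = np.full(graph.n_nodes, -1, dtype=np.int64)
    remap[member_nodes] = np.arange(member_nodes.size)
    emask = remap[graph.edges[:, 0]] >= 0
    ei = remap[graph.edges[emask, 0]]
    ej = remap[graph.edges[emask, 1]]
    ew = graph.weights[emask]
    k = member_nodes.size
    q = remap[query_nodes]
    if k == 1:
        return np.zeros((1, 1))
    deg = np.bincount(ei, weights=ew, minlength=k) + \
        np.bincount(ej, weights=ew, minlength=k)
    lap = coo_matrix(
        (np.concatenate([-ew, -ew, deg]),
         (np.concatenate([ei, ej, np.arange(k)]),
          np.concatenate([ej, ei, np.arange(k)]))),
        shape=(k, k)).tocsc()
    # ground the last node of the component
    ground = k - 1
    keep = np.arange(k) != ground
    red = lap[keep][:, keep].tocsc()
    lu = splu(red)
    # potentials for unit injection at each query node (ground as sink)
    pos_in_red = np.cumsum(keep) - 1  # position of node within reduced system
    m = q.size
    v = np.zeros((m, k))
    for t, node in enumerate(q):
        rhs = np.zeros(k - 1)
        if node != ground:
            rhs[pos_in_red[node]] = 1.0
        sol = lu.solve(rhs)
        v[t, keep] = sol
    # R(i, j) = v_i[i] + v_j[j] - v_i[j] - v_j[i]
    vii = v[np.arange(m), q]
    res = vii[:, None] + vii[None, :] - v[:, q] - v[:, q].T
    np.fill_diagonal(res, 0.0)
    return np.maximum(res, 0.0)


def geographic_distance(lons, lats) -> np.ndarray:
    """Great-circle distance matrix in km."""
    lons, lats = validate_coords(lons, lats)
    if lons.size < 2:
        raise ValueError("need >= 2 locations")
    return pairwise_haversine_km(lons, lats)


def normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Linearly rescale the finite off-diagonal values to [0, 1]; the
    diagonal stays 0 and infinities are preserved."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(matrix)
    vals = matrix[finite]
    if vals.size < 2 or vals.max() == vals.min():
        raise ValueError("need >= 2 distinct finite off-diagonal values")
    out = matrix.copy()
    out[finite] = (vals - vals.min()) / (vals.max() - vals.min())
    np.fill_diagonal(out, 0.0)
    return out


def vif(matrices: Sequence[np.ndarray]) -> list[float]:
    """Variance inflation factor of each matrix's off-diagonal vector
    regressed (with intercept) on the others'. VIF = 1 / (1 - R^2)."""
    if len(matrices) < 2:
        raise ValueError("need >= 2 matrices")
    n = matrices[0].shape[0]
    iu = np.triu_indices(n, k=1)
    vectors = [np.asarray(m, dtype=float)[iu] for m in matrices]
    out = []
    for k, y in enumerate(vectors):
        others = [v for t, v in enumerate(vectors) if t != k]
        design = np.column_stack([np.ones_like(y)] + others)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            out.append(float("inf"))
            continue
        r2 = 1.0 - np.sum(resid ** 2) / sst
        out.append(float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return out
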