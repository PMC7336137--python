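"""Weighted graph measures on thresholded connectivity matrices.

Edge lengths are inverse connection strengths; shortest paths use
Dijkstra.  Global measures: global efficiency (GE, mean inverse shortest
path length over ordered node pairs, with 0 contributed by disconnected
pairs), characteristic path length (CPL, mean shortest path length over
*connected* pairs only) and transitivity (T, collectively normalised
Onnela weighted triangle density with weights rescaled by the maximum).
Nodal measures: clustering coefficient (CC, per-node Onnela triangle
geometric mean), nodal efficiency (NE), betweenness centrality (BC,
Brandes with a relative tolerance for equal-length path counting,
normalised by (N-1)(N-2)) and eigenvector centrality (EVC, unit-norm
nonnegative principal eigenvector of the weighted matrix).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .atlas import AtlasTable, hemisphere_blocks

PATH_TIE_RTOL = 1e-10


@dataclass
class ThresholdedGraph:
    """Proportionally thresholded weighted graph with inverse-weight lengths."""

    weights: np.ndarray
    density: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            lens = np.where(self.weights > 0, 1.0 / self.weights, np.inf)
        np.fill_diagonal(lens, 0.0)
        return lens


@dataclass
class GlobalMeasures:
    ge: float
    cpl: float
    transitivity: float
    network: str = "whole"
    band: str = ""


@dataclass
class NodalMeasures:
    cc: np.ndarray
    ne: np.ndarray
    bc: np.ndarray
    evc: np.ndarray


def extract_quadrant(
    adj: np.ndarray, atlas: AtlasTable, side: str
) -> np.ndarray:
    """Principal 123x123 submatrix for one hemisphere's nodes.

    ``adj`` must be in canonical atlas order (position = node_id - 1).
    """
    adj = np.asarray(adj)
    if adj.shape != (len(atlas), len(atlas)):
        raise ValueError(f"adjacency must be {len(atlas)}x{len(atlas)}")
    left, right = hemisphere_blocks(atlas)
    ids = {"left": left, "right": right}.get(side)
    if ids is None:
        raise ValueError("side must be 'left' or 'right'")
    pos = np.asarray(ids, dtype=int) - 1
    return adj[np.ix_(pos, pos)]


def proportional_threshold(adj: np.ndarray, density: float = 0.10) -> ThresholdedGraph:
    """Keep the strongest fraction of edges.

    Retains ``round(density * N(N-1)/2)`` strongest upper-triangle edges,
    ties broken by smaller (i, j) lexicographic index, zeroes the rest and
    symmetrises.  Retained edge weights are unchanged.
    """
    adj = np.asarray(adj, dtype=float)
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(adj < 0):
        raise ValueError("adjacency must be nonnegative")
    n = adj.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = adj[iu, ju]
    m = int(round(density * n * (n - 1) / 2))
    order = np.lexsort((ju, iu, -w))
    keep = order[:m]
    out = np.zeros_like(adj)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return ThresholdedGraph(out, density)


def absolute_threshold(adj: np.ndarray, cutoff: float = 0.1) -> ThresholdedGraph:
    """Keep edges whose weight exceeds an absolute cutoff.

    Alternative to :func:`proportional_threshold` for analyses defined by a
    fixed connectivity value rather than a target density.
    """
    adj = np.asarray(adj, dtype=float)
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(adj < 0):
        raise ValueError("adjacency must be nonnegative")
    out = np.where(adj > cutoff, adj, 0.0)
    np.fill_diagonal(out, 0.0)
    n = adj.shape[0]
    density = float(np.count_nonzero(np.triu(out, 1)) / (n * (n - 1) / 2))
    return ThresholdedGraph(out, density)


def shortest_path_lengths(g: ThresholdedGraph) -> np.ndarray:
    """All-pairs weighted shortest distances (inf for disconnected pairs)."""
    lens = g.lengths
    if np.any(g.weights < 0):
        raise ValueError("weights must be nonnegative")
    finite = np.where(np.isfinite(lens), lens, 0.0)
    graph = csr_matrix(finite)
    d = _sp_dijkstra(graph, directed=False)
    return d


def _triangle_terms(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Onnela triangle intensity t_i and binary degree k_i."""
    w = np.asarray(weights, dtype=float)
    mx = w.max()
    what = w / mx if mx > 0 else w
    c = np.cbrt(what)
    t = np.diag(c @ c @ c) / 2.0
    k = (w > 0).sum(axis=1)
    return t, k


def global_measures(
    g: ThresholdedGraph, network: str = "whole", band: str = ""
) -> GlobalMeasures:
    """GE, CPL and transitivity of a thresholded graph."""
    n = g.n_nodes
    d = shortest_path_lengths(g)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    ge = float(inv[off].mean()) if n > 1 else 0.0
    finite = np.isfinite(d) & off
    if finite.any():
        cpl = float(d[finite].mean())
    else:
        warnings.warn("graph has no connected pairs; CPL undefined")
        cpl = float("nan")
    t, k = _triangle_terms(g.weights)
    denom = float((k * (k - 1)).sum())
    trans = float(2.0 * t.sum() / denom) if denom > 0 else 0.0
    return GlobalMeasures(ge, cpl, trans, network, band)


def _brandes_betweenness(weights: np.ndarray, rtol: float = PATH_TIE_RTOL) -> np.ndarray:
    """Weighted betweenness via Brandes' algorithm.

    Dijkstra from every source; predecessor relaxation treats distances
    equal within a relative tolerance as ties, so shortest-path counts are
    reproducible under floating-point noise.  Returns raw (unnormalised)
    betweenness for an undirected graph.
    """
    n = weights.shape[0]
    with np.errstate(divide="ignore"):
        lens = np.where(weights > 0, 1.0 / weights, np.inf)
    nbrs = [np.flatnonzero(weights[i] > 0) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        order: list[int] = []
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v in nbrs[u]:
                if done[v]:
                    continue
                alt = dist[u] + lens[u, v]
                tol = rtol * max(abs(alt), 1.0)
                if alt < dist[v] - tol:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif abs(alt - dist[v]) <= tol:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    return bc / 2.0  # each undirected pair counted from both endpoints


def nodal_measures(g: ThresholdedGraph, normalized_bc: bool = True) -> NodalMeasures:
    """CC, NE, BC and EVC per node."""
    n = g.n_nodes
    w = g.weights
    t, k = _triangle_terms(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(k >= 2, 2.0 * t / np.where(k >= 2, k * (k - 1), 1.0), 0.0)
    d = shortest_path_lengths(g)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    bc = _brandes_betweenness(w)
    if normalized_bc and n > 2:
        # undirected source-target pair counts divided by (N-1)(N-2), so a
        # 3-path's middle node scores 0.5
        bc = bc / ((n - 1) * (n - 2))
    evals, evecs = np.linalg.eigh(w)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    nrm = np.linalg.norm(v)
    evc = v / nrm if nrm > 0 else v
    return NodalMeasures(cc, ne, bc, evc)
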