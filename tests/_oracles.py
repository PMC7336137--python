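"""Brute-force reference implementations used as test oracles.

Deliberately simple and slow: triangle enumeration, Floyd-Warshall with
explicit equal-path counting, exhaustive dwPLI pair enumeration.  These are
independent of the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TIE_RTOL = 1e-10


def dwpli_enumeration(im: np.ndarray) -> float:
    """dwPLI by direct enumeration of all ordered trial pairs j != k."""
    im = np.asarray(im, dtype=float)
    num = 0.0
    den = 0.0
    for j in range(len(im)):
        for k in range(len(im)):
            if j == k:
                continue
            num += im[j] * im[k]
            den += abs(im[j] * im[k])
    return num / den if den > 0 else 0.0


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = np.array(lengths, dtype=float)
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _path_counts(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(distances, sigma[s,t], sigma_through[s,t,v]) by exhaustive DFS.

    Enumerates every simple path between every ordered pair and keeps those
    whose length ties the shortest within TIE_RTOL.  Exponential; only for
    tiny graphs.
    """
    n = lengths.shape[0]
    dist = floyd_warshall(lengths)
    sigma = np.zeros((n, n))
    through = np.zeros((n, n, n))
    adj = [
        [j for j in range(n) if j != i and np.isfinite(lengths[i, j])]
        for i in range(n)
    ]

    def dfs(path, length, target, budget):
        v = path[-1]
        if v == target:
            yield list(path), length
            return
        for w in adj[v]:
            if w in path:
                continue
            nl = length + lengths[v, w]
            if nl <= budget * (1 + TIE_RTOL) + 1e-300:
                path.append(w)
                yield from dfs(path, nl, target, budget)
                path.pop()

    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            budget = dist[s, t]
            for path, length in dfs([s], 0.0, t, budget):
                if abs(length - budget) <= TIE_RTOL * max(abs(budget), 1.0):
                    sigma[s, t] += 1
                    for v in path[1:-1]:
                        through[s, t, v] += 1
    return dist, sigma, through


def global_measures_bruteforce(weights: np.ndarray) -> tuple[float, float, float]:
    """(GE, CPL, T) by direct enumeration."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = floyd_warshall(lengths)
    inv = []
    finite = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            inv.append(1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0)
            if np.isfinite(d[i, j]):
                finite.append(d[i, j])
    ge = float(np.mean(inv)) if inv else 0.0
    cpl = float(np.mean(finite)) if finite else float("nan")

    wmax = w.max()
    t_num = 0.0
    k_den = 0.0
    if wmax > 0:
        wh = w / wmax
        for i in range(n):
            t_i = 0.0
            for j in range(n):
                for h in range(n):
                    if j == i or h == i or j == h:
                        continue
                    t_i += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
            t_i /= 2.0
            k = int(np.count_nonzero(w[i]))
            t_num += 2.0 * t_i
            k_den += k * (k - 1)
    t = t_num / k_den if k_den > 0 else 0.0
    return ge, cpl, float(t)


def nodal_measures_bruteforce(
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(CC, NE, BC, EVC) by direct enumeration; BC normalised by (N-1)(N-2)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist, sigma, through = _path_counts(lengths)

    wmax = w.max()
    cc = np.zeros(n)
    if wmax > 0:
        wh = w / wmax
        for i in range(n):
            t_i = 0.0
            for j in range(n):
                for h in range(n):
                    if j == i or h == i or j == h:
                        continue
                    t_i += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
            t_i /= 2.0
            k = int(np.count_nonzero(w[i]))
            cc[i] = 2.0 * t_i / (k * (k - 1)) if k >= 2 else 0.0

    ne = np.zeros(n)
    for i in range(n):
        vals = [
            1.0 / dist[i, j] if np.isfinite(dist[i, j]) else 0.0
            for j in range(n)
            if j != i
        ]
        ne[i] = float(np.mean(vals)) if vals else 0.0

    bc = np.zeros(n)
    for v in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(n):
                if s == t or s == v or t == v or sigma[s, t] == 0:
                    continue
                acc += through[s, t, v] / sigma[s, t]
        bc[v] = acc / 2.0  # undirected: each unordered pair counted once
    bc /= (n - 1) * (n - 2)

    evals, evecs = np.linalg.eigh(w)
    evc = evecs[:, -1]
    if evc.sum() < 0:
        evc = -evc
    evc = np.clip(evc, 0.0, None)
    nrm = np.linalg.norm(evc)
    if nrm > 0:
        evc = evc / nrm
    return cc, ne, bc, evc


def components_bfs(edges: list[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Connected components of an edge list, as sets of edges, via BFS."""
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        queue = [start]
        nodes = {start}
        seen.add(start)
        while queue:
            v = queue.pop()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    nodes.add(u)
                    queue.append(u)
        comps.append(
            {(i, j) for i, j in edges if i in nodes and j in nodes}
        )
    return comps


def random_threshold_graph(
    rng: np.random.Generator, n: int, density: float
) -> np.ndarray:
    """Random symmetric weighted graph with approximately the given density."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    keep = rng.random(iu.size) < density
    vals = rng.uniform(0.1, 1.0, iu.size)
    w[iu[keep], ju[keep]] = vals[keep]
    return w + w.T
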