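"""Network-based statistics (NBS) for two-group connectome comparison.

A pooled-variance two-sample t-test is run on every connection; edges
exceeding a primary threshold form a graph whose connected components
("clusters") are the candidate subnetworks.  Group labels are permuted
many times, the largest component extent (edge count) is recorded per
permutation, and each observed component's family-wise-error-corrected
p-value is the fraction of permutations whose maximum extent reaches its
extent, with the (k + 1) / (P + 1) convention so p-values are never zero.

Thresholding is one-sided per direction; ``direction="both"`` runs the two
one-sided analyses separately (each against its own permutation null)
and reports both, since a single NBS family is defined per contrast
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

T_SENTINEL = 1e12  # stands in for +/- infinite t (zero variance, unequal means)


@dataclass(frozen=True)
class NBSConfig:
    primary_threshold: float = 3.45
    n_permutations: int = 5000
    alpha: float = 0.05
    direction: str = "both"  # A_gt_B, B_gt_A, both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_threshold <= 0:
            raise ValueError("primary threshold must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.direction not in ("A_gt_B", "B_gt_A", "both"):
            raise ValueError("direction must be A_gt_B, B_gt_A or both")


@dataclass
class NBSComponent:
    edges: list[tuple[int, int, float]]  # (i, j, t) with i < j, 1-based node ids
    nodes: set[int]  # 1-based node ids (atlas convention)
    extent: int
    fwer_p: float
    direction: str


@dataclass
class NBSResult:
    components: list[NBSComponent]
    null_max_extents: dict[str, np.ndarray]
    t_matrix: np.ndarray
    config: NBSConfig

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.fwer_p < self.config.alpha]

    def summary(self) -> dict:
        return {
            "config": {
                "primary_threshold": self.config.primary_threshold,
                "n_permutations": self.config.n_permutations,
                "alpha": self.config.alpha,
                "direction": self.config.direction,
                "seed": self.config.seed,
            },
            "components": [
                {
                    "direction": c.direction,
                    "extent": c.extent,
                    "n_nodes": len(c.nodes),
                    "fwer_p": c.fwer_p,
                }
                for c in self.components
            ],
        }


def _stack_upper(group: list[np.ndarray]) -> tuple[np.ndarray, int]:
    mats = [np.asarray(m, dtype=float) for m in group]
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all matrices must share the same shape")
    iu = np.triu_indices(n, 1)
    return np.stack([m[iu] for m in mats], axis=0), n


def _pooled_t(x: np.ndarray, n1: int) -> np.ndarray:
    """Vectorised pooled two-sample t over columns; rows 0..n1-1 are group A."""
    n = x.shape[0]
    n2 = n - n1
    a, b = x[:n1], x[n1:]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    var = (ssa + ssb) / (n - 2)
    se = np.sqrt(var * (1.0 / n1 + 1.0 / n2))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            se > 0,
            diff / np.where(se > 0, se, 1.0),
            np.where(diff == 0, 0.0, np.sign(diff) * T_SENTINEL),
        )
    return t


def edge_tstats(
    group_a: list[np.ndarray], group_b: list[np.ndarray]
) -> np.ndarray:
    """Pooled-variance two-sample t per edge, as a symmetric matrix."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    xa, n = _stack_upper(group_a)
    xb, nb_n = _stack_upper(group_b)
    if nb_n != n:
        raise ValueError("groups have different node counts")
    t = _pooled_t(np.concatenate([xa, xb], axis=0), len(group_a))
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    out[iu] = t
    out = out + out.T
    return out


def suprathreshold_components(
    t_matrix: np.ndarray, threshold: float, direction: str = "A_gt_B"
) -> list[NBSComponent]:
    """Connected components of the supra-threshold edge graph."""
    t = np.asarray(t_matrix, dtype=float)
    n = t.shape[0]
    iu, ju = np.triu_indices(n, 1)
    tv = t[iu, ju]
    if direction == "A_gt_B":
        mask = tv > threshold
    elif direction == "B_gt_A":
        mask = -tv > threshold
    else:
        raise ValueError("direction must be one-sided here")
    ei, ej, et = iu[mask], ju[mask], tv[mask]
    if ei.size == 0:
        return []
    g = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n, n))
    n_comp, labels = connected_components(g, directed=False)
    comps: dict[int, NBSComponent] = {}
    for i, j, tval in zip(ei, ej, et):
        lab = labels[i]
        c = comps.get(lab)
        if c is None:
            c = NBSComponent([], set(), 0, 1.0, direction)
            comps[lab] = c
        c.edges.append((int(i) + 1, int(j) + 1, float(tval)))
        c.nodes.update((int(i) + 1, int(j) + 1))
        c.extent += 1
    return sorted(comps.values(), key=lambda c: -c.extent)


def _max_extent(ei: np.ndarray, ej: np.ndarray, n: int) -> int:
    """Largest connected-component edge count of an edge list (union-find)."""
    if ei.size == 0:
        return 0
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(ei, ej):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    counts: dict[int, int] = {}
    for i in ei:
        r = find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def nbs_test(
    group_a: list[np.ndarray],
    group_b: list[np.ndarray],
    config: NBSConfig = NBSConfig(),
    _chunk: int = 128,
) -> NBSResult:
    """Full NBS permutation test.

    Subjects are relabelled between groups preserving group sizes; the
    maximum supra-threshold component extent per permutation forms the
    null distribution.  Deterministic given ``config.seed``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    xa, n = _stack_upper(group_a)
    xb, _ = _stack_upper(group_b)
    x = np.concatenate([xa, xb], axis=0)
    n1 = len(group_a)
    n_sub = x.shape[0]
    iu, ju = np.triu_indices(n, 1)

    t_obs = _pooled_t(x, n1)
    t_mat = np.zeros((n, n))
    t_mat[iu, ju] = t_obs
    t_mat = t_mat + t_mat.T

    directions = (
        ["A_gt_B", "B_gt_A"] if config.direction == "both" else [config.direction]
    )
    observed = {
        d: suprathreshold_components(t_mat, config.primary_threshold, d)
        for d in directions
    }

    rng = np.random.default_rng(config.seed)
    perms = np.stack(
        [rng.permutation(n_sub) for _ in range(config.n_permutations)], axis=0
    )
    thr = config.primary_threshold
    null_max = {d: np.zeros(config.n_permutations, dtype=int) for d in directions}
    tot = x.sum(axis=0)
    tot_sq = (x**2).sum(axis=0)
    n2 = n_sub - n1
    inv = 1.0 / n1 + 1.0 / n2
    # t > thr  <=>  diff > 0 and diff^2 (n-2) > thr^2 inv ssq, where
    # ssq = tot_sq - s1^2/n1 - (tot-s1)^2/n2 is the pooled sum of squares;
    # avoids sqrt and division inside the permutation loop.
    coef = thr * thr * inv / (n_sub - 2)
    for start in range(0, config.n_permutations, _chunk):
        sel = perms[start : start + _chunk, :n1]  # chunk x n1
        p = np.zeros((sel.shape[0], n_sub))
        np.put_along_axis(p, sel, 1.0, axis=1)
        s1 = p @ x
        s2 = tot - s1
        diff = s1 * (1.0 / n1) - s2 * (1.0 / n2)
        ssq = tot_sq - s1 * s1 * (1.0 / n1) - s2 * s2 * (1.0 / n2)
        np.clip(ssq, 0.0, None, out=ssq)
        rhs = coef * ssq
        dsq = diff * diff
        for d in directions:
            sgn = diff > 0 if d == "A_gt_B" else diff < 0
            supra = sgn & (dsq > rhs)
            for r in range(supra.shape[0]):
                cols = np.flatnonzero(supra[r])
                null_max[d][start + r] = _max_extent(iu[cols], ju[cols], n)

    components: list[NBSComponent] = []
    for d in directions:
        null = null_max[d]
        for c in observed[d]:
            k = int((null >= c.extent).sum())
            c.fwer_p = (1 + k) / (config.n_permutations + 1)
            components.append(c)
    components.sort(key=lambda c: -c.extent)
    return NBSResult(components, {d: null_max[d] for d in directions}, t_mat, config)


def save_result(result: NBSResult, edge_tsv_path, summary_json_path) -> None:
    """Write component edges (node_i, node_j, t; 1-based ids) and a summary."""
    import json

    with open(edge_tsv_path, "w") as f:
        f.write("component\tdirection\tnode_i\tnode_j\tt\n")
        for ci, c in enumerate(result.components):
            for i, j, t in c.edges:
                f.write(f"{ci}\t{c.direction}\t{i}\t{j}\t{t:.6g}\n")
    with open(summary_json_path, "w") as f:
        json.dump(result.summary(), f, indent=2)
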