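"""Group comparison statistics and cohort-matching tests.

Covers the statistical battery around the graph measures: Wilcoxon
rank-sum comparisons with Benjamini-Hochberg FDR adjustment across bands,
measures and hemispheres; the demographic matching tests for two patient
groups (pooled two-sample t from summary statistics, Fisher's exact test
for 2x2 tables, the Freeman-Halton extension for r x c tables by full
enumeration, and Wilcoxon for ordinal counts); and per-area node summaries
over the 48-area grouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasTable


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have at most 10 observations and
    there are no ties; the normal approximation with tie and continuity
    correction otherwise.  Returns (rank-sum statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if x.size <= 10 and y.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sst.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank sum of x
    return w, float(res.pvalue)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ttest_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Pooled-variance two-sided t-test from group summary statistics."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    res = sst.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    _check_counts(t)
    return float(sst.fisher_exact(t, alternative="two-sided")[1])


def _check_counts(t: np.ndarray) -> None:
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValueError("contingency table must hold nonnegative integers")


def _log_table_prob(table: np.ndarray, lgam_margins: float, lgam_n: float) -> float:
    return lgam_margins - lgam_n - sum(
        math.lgamma(v + 1) for v in table.ravel()
    )


def freeman_halton(table) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (with a small relative slack against floating-point noise).
    Feasible for the small tables of a cohort-matching battery.
    """
    t = np.asarray(table, dtype=float)
    _check_counts(t)
    t = t.astype(int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lgam_margins = sum(math.lgamma(v + 1) for v in rows) + sum(
        math.lgamma(v + 1) for v in cols
    )
    lgam_n = math.lgamma(n + 1)
    lp_obs = _log_table_prob(t, lgam_margins, lgam_n)

    r, c = t.shape
    total = 0.0
    # enumerate tables row by row with running column remainders
    def recurse(row_idx: int, col_rem: np.ndarray, lp_acc: float) -> None:
        nonlocal total
        if row_idx == r - 1:
            # last row forced
            if np.any(col_rem < 0):
                return
            lp = (
                lp_acc
                - sum(math.lgamma(v + 1) for v in col_rem)
                + lgam_margins
                - lgam_n
            )
            if lp <= lp_obs + 1e-7:
                total += math.exp(lp)
            return
        target = rows[row_idx]
        ranges = [range(0, min(target, col_rem[j]) + 1) for j in range(c - 1)]
        for combo in product(*ranges):
            s = sum(combo)
            if s > target:
                continue
            last = target - s
            if last > col_rem[c - 1]:
                continue
            cells = list(combo) + [last]
            lp_row = -sum(math.lgamma(v + 1) for v in cells)
            recurse(
                row_idx + 1,
                col_rem - np.array(cells),
                lp_acc + lp_row,
            )

    recurse(0, cols.copy(), 0.0)
    return float(min(total, 1.0))


@dataclass
class MatchingTestResult:
    variable: str
    test: str
    statistic: float | None
    p_value: float


def cohort_matching_tests(
    continuous: dict[str, tuple[int, float, float, int, float, float]] | None = None,
    fisher_tables: dict[str, np.ndarray] | None = None,
    freeman_halton_tables: dict[str, np.ndarray] | None = None,
    ranksum_samples: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> list[MatchingTestResult]:
    """Cohort-matching battery for two patient groups.

    ``continuous`` maps variable name to (n1, mean1, sd1, n2, mean2, sd2)
    summary statistics (pooled two-sample t); ``fisher_tables`` holds 2x2
    tables; ``freeman_halton_tables`` r x c tables; ``ranksum_samples``
    raw value pairs for the Wilcoxon rank-sum test.
    """
    out: list[MatchingTestResult] = []
    for name, args in (continuous or {}).items():
        t, p = ttest_from_summary(*args)
        out.append(MatchingTestResult(name, "two-sample t", t, p))
    for name, tab in (fisher_tables or {}).items():
        out.append(
            MatchingTestResult(name, "Fisher exact", None, fisher_exact_2x2(tab))
        )
    for name, tab in (freeman_halton_tables or {}).items():
        out.append(
            MatchingTestResult(name, "Freeman-Halton", None, freeman_halton(tab))
        )
    for name, (x, y) in (ranksum_samples or {}).items():
        w, p = wilcoxon_ranksum(x, y)
        out.append(MatchingTestResult(name, "Wilcoxon rank-sum", w, p))
    return out


# ---------------------------------------------------------------------------
# feature comparison across groups

def compare_feature_table(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    label_col: str = "label",
) -> pd.DataFrame:
    """Wilcoxon rank-sum per feature column between two groups, BH-FDR adjusted.

    Returns a DataFrame with columns feature, statistic, p, p_fdr and the
    sign of the (a - b) median difference.
    """
    feat_cols = [c for c in features.columns if c not in (label_col, "subject_id")]
    a = features[features[label_col] == group_a]
    b = features[features[label_col] == group_b]
    rows = []
    for c in feat_cols:
        w, p = wilcoxon_ranksum(a[c].to_numpy(), b[c].to_numpy())
        sign = float(np.sign(np.median(a[c]) - np.median(b[c])))
        rows.append({"feature": c, "statistic": w, "p": p, "direction": sign})
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_bh(df["p"].to_numpy())
    return df


def area_summary(
    node_ids, atlas: AtlasTable, flag_sets: dict[str, set[int]] | None = None
) -> pd.DataFrame:
    """Counts of flagged nodes per 48 areas, with pairwise overlap counts.

    ``node_ids`` is the base flag set (e.g. NBS subnetwork nodes, 1-based);
    ``flag_sets`` optionally maps measure names to further node sets, each
    counted per area alongside the base set.
    """
    sets = {"nodes": set(int(i) for i in node_ids)}
    if flag_sets:
        sets.update({k: set(int(i) for i in v) for k, v in flag_sets.items()})
    valid = set(int(i) for i in atlas.node_ids)
    for name, s in sets.items():
        unknown = s - valid
        if unknown:
            raise ValueError(f"unknown node ids in {name}: {sorted(unknown)}")
    df = atlas.table
    areas = df[["hemisphere", "area_group"]].drop_duplicates()
    rows = []
    for _, (hemi, area) in areas.iterrows():
        members = set(
            int(i)
            for i in df.loc[
                (df["hemisphere"] == hemi) & (df["area_group"] == area), "node_id"
            ]
        )
        row = {"hemisphere": hemi, "area_group": area, "n_nodes": len(members)}
        for name, s in sets.items():
            row[name] = len(s & members)
        names = list(sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                row[f"{names[i]}&{names[j]}"] = len(
                    sets[names[i]] & sets[names[j]] & members
                )
        rows.append(row)
    return pd.DataFrame(rows)
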