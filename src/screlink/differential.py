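"""Wilcoxon rank-sum differential expression and gene-set enrichment.

The DE test mirrors the standard single-cell marker workflow: per-group
downsampling, detection-fraction and fold-change pre-filters, a two-sided
rank-sum test per gene, and Benjamini-Hochberg adjustment over the tested
genes only. Fold change uses the de-logged-mean-plus-pseudocount
convention: ``log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1))``.

The rank-sum p-value uses the tie-corrected normal approximation, or — for
small tie-free samples — the exact null distribution of the rank sum,
computed by dynamic programming (equivalent to full enumeration of group
assignments). Two-sided exact p is ``P(|W - E[W]| >= |w - E[W]|)``.

Gene-set enrichment is the upper-tail hypergeometric (over-representation)
test with BH q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "benjamini_hochberg",
    "rank_sum_test",
    "wilcoxon_de",
    "hypergeom_enrich",
]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH: ``q_(i) = min_{j>=i}(p_(j) * m / j)`` clipped at 1,
    returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_exact_p(w: float, n1: int, n2: int) -> float:
    """Exact two-sided p for the rank-sum W of the first group (no ties):
    P(|W - E| >= |w - E|) under uniform assignment of ranks.

    The null distribution is built by DP over "which of the n1+n2 ranks go
    to group 1", equivalent to exhaustive enumeration of all C(n1+n2, n1)
    assignments.
    """
    n = n1 + n2
    # dp[k][s] = number of k-subsets of ranks 1..i with sum s
    max_sum = n1 * n + 1
    dp = np.zeros((n1 + 1, max_sum))
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            dp[k, rank:] += dp[k - 1, : max_sum - rank]
    counts = dp[n1]
    total = counts.sum()
    e = n1 * (n + 1) / 2.0
    dev = abs(w - e)
    sums = np.arange(max_sum)
    extreme = np.abs(sums - e) >= dev - 1e-9
    return float(counts[extreme].sum() / total)


def rank_sum_test(
    a: np.ndarray, b: np.ndarray, method: str = "auto", exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` with W the rank sum of ``a`` (midranks for ties).
    ``method``: "exact" (tie-free small samples), "asymptotic"
    (tie-corrected normal approximation with continuity correction), or
    "auto" (exact when both groups are <= ``exact_max_n`` and there are no
    ties).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and max(n1, n2) <= exact_max_n
    )
    if use_exact:
        if has_ties:
            raise ValueError("exact rank-sum p undefined with ties")
        return w, _rank_sum_exact_p(w, n1, n2)
    n = n1 + n2
    e = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - e) - 0.5) / np.sqrt(var)     # continuity-corrected
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def wilcoxon_de(
    lognorm,
    group_a,
    group_b,
    genes: list[str],
    logfc_threshold: float = 0.25,
    min_pct: float = 0.5,
    min_diff_pct: float = 0.25,
    max_cells_per_ident: int = 500,
    padj_max: float = 0.01,
    seed: int = 0,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Rank-sum DE between two cell groups of a normalized matrix.

    ``group_a``/``group_b`` are disjoint row-index arrays (each >= 3 cells),
    downsampled to ``max_cells_per_ident`` with the given seed. A gene is
    tested iff ``max(pct_a, pct_b) >= min_pct`` AND ``|pct_a - pct_b| >=
    min_diff_pct`` AND ``|log2fc| >= logfc_threshold``. BH runs over tested
    genes only; rows with ``padj < padj_max`` are returned, sorted by padj
    then gene id.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size < 3 or group_b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    rng = np.random.default_rng(seed)
    if group_a.size > max_cells_per_ident:
        group_a = np.sort(rng.choice(group_a, max_cells_per_ident, replace=False))
    if group_b.size > max_cells_per_ident:
        group_b = np.sort(rng.choice(group_b, max_cells_per_ident, replace=False))
    X = lognorm.toarray() if sp.issparse(lognorm) else np.asarray(lognorm, float)
    A, B = X[group_a], X[group_b]
    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    tested = (
        (np.maximum(pct_a, pct_b) >= min_pct)
        & (np.abs(pct_a - pct_b) >= min_diff_pct)
        & (np.abs(log2fc) >= logfc_threshold)
    )
    idx = np.flatnonzero(tested)
    pvals = np.ones(idx.size)
    for j, gi in enumerate(idx):
        _, pvals[j] = rank_sum_test(A[:, gi], B[:, gi], method=method)
    padj = benjamini_hochberg(pvals)
    gene_arr = np.asarray(genes, dtype=object)
    df = pd.DataFrame(
        {
            "gene_id": gene_arr[idx],
            "log2fc": log2fc[idx],
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "p": pvals,
            "padj": padj,
        }
    )
    df = df[df["padj"] < padj_max]
    df = df.sort_values(["padj", "gene_id"], kind="stable").reset_index(drop=True)
    df.attrs["n_tested"] = int(idx.size)
    return df


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    ``p = P(X >= n_overlap)`` with population ``n_universe``, successes
    ``n_set`` (the set intersected with the universe), draws ``n_query``;
    q is BH across sets; ``fold_enrichment = (overlap/query)/(set/universe)``.
    Rows with ``q <= q_max`` are returned sorted by q then set id.
    """
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValueError("universe contains duplicates")
    qset = set(query)
    stray = sorted(qset - uni)
    if stray:
        raise ValueError(f"query genes missing from universe: {stray[:10]}")
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        k = len(qset & members)
        n_set = len(members)
        p = float(stats.hypergeom.sf(k - 1, len(uni), n_set, len(qset)))
        fold = (
            (k / len(qset)) / (n_set / len(uni)) if n_set and len(qset) else 0.0
        )
        rows.append((set_id, k, len(qset), n_set, len(uni), p, fold))
    df = pd.DataFrame(
        rows,
        columns=["set_id", "n_overlap", "n_query", "n_set", "n_universe", "p",
                 "fold_enrichment"],
    )
    df["q"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    df = df[df["q"] <= q_max]
    return df.sort_values(["q", "set_id"], kind="stable").reset_index(drop=True)
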