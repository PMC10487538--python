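"""Peak merging, peak annotation, metacells, and peak-to-gene linkage.

This is the analysis core: per-cluster pseudobulk peak calls are merged into
a universal fixed-width peak set by iterative overlap removal; peaks are
classified against gene models (promoter > exonic > intronic > distal);
low-overlapping aggregates of ~100 similar cells ("metacells") are built by
k-nearest neighbors in the LSI space; peak accessibility is correlated with
imputed gene expression across metacells for all candidate pairs within a
cis window; p-values come from the t-transform of the Pearson r and are
BH-adjusted across all tested pairs; the surviving distal links are grouped
into k-means clusters labeled by their most-enriched cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io_intervals import CountsMatrix, GeneModel, GenomicInterval, PeakSet
from .reduce_cluster import ReducedSpace, log_normalize

__all__ = [
    "MetacellGrouping",
    "iterative_overlap_merge",
    "call_cluster_peaks",
    "peak_matrix_from_tiles",
    "annotate_peak",
    "annotate_peaks",
    "make_metacells",
    "aggregate_metacells",
    "correlate_peak_gene",
    "filter_links",
    "kmeans_links",
]

LINK_COLUMNS = ["peak_id", "gene_id", "r", "p", "fdr", "distance_bp", "peak_class"]


# ---------------------------------------------------------------------------
# Universal peak set
# ---------------------------------------------------------------------------

def iterative_overlap_merge(peak_lists: list[PeakSet], fixed_width: int | None = 500) -> PeakSet:
    """Merge per-cluster peak calls into a universal set by iterative
    overlap removal: repeatedly keep the best-scoring remaining peak and
    drop every peak overlapping it. Ties break by (chrom, start, end, id).
    """
    pool = []
    for ps in peak_lists:
        for iv in ps:
            if iv.score is None:
                raise ValueError(f"peak {iv.id} has no score")
            pool.append(iv)
    # order by descending score, canonical tie-break
    pool.sort(key=lambda iv: (-iv.score, iv.chrom, iv.start, iv.end, iv.id or ""))
    kept: list[GenomicInterval] = []
    active: dict[str, list] = {}
    for iv in pool:
        overlapping = False
        for s, e in active.get(iv.chrom, []):
            if iv.start < e and s < iv.end:
                overlapping = True
                break
        if overlapping:
            continue
        kept.append(iv)
        active.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # dedupe ids across clusters: the retained interval keeps the best score
    seen = {}
    for iv in kept:
        key = (iv.chrom, iv.start, iv.end)
        if key not in seen:
            seen[key] = iv
    return PeakSet(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, score=iv.score)
            for iv in seen.values()
        ],
        fixed_width=fixed_width,
    )


def call_cluster_peaks(
    tiles: CountsMatrix,
    cluster_labels,
    mean_count_min: float = 0.45,
) -> dict:
    """Naive pseudobulk peak caller for fixtures: a tile is a peak of a
    cluster when its mean count per cell in that cluster reaches
    ``mean_count_min``; the score is that mean. Real per-cluster peak calls
    can be supplied instead wherever a list of scored PeakSets is accepted.
    """
    from .qc import _parse_tile_coords

    chroms, starts, ends = _parse_tile_coords(tiles.features)
    labels = np.asarray(cluster_labels)
    out = {}
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        mean = np.asarray(tiles.X[rows].mean(axis=0)).ravel()
        idx = np.flatnonzero(mean >= mean_count_min)
        ivs = [
            GenomicInterval(
                str(chroms[i]), int(starts[i]), int(ends[i]), score=float(mean[i])
            )
            for i in idx
        ]
        out[c] = PeakSet(ivs)
    return out


def peak_matrix_from_tiles(tiles: CountsMatrix, peaks: PeakSet) -> CountsMatrix:
    """Cells x peaks counts: sum of tile counts overlapping each peak."""
    W = _peak_weight_matrix(tiles, peaks)
    X = sp.csr_matrix(tiles.X @ W)
    out = CountsMatrix.__new__(CountsMatrix)
    out.X = X
    out.barcodes = list(tiles.barcodes)
    out.features = list(peaks.ids)
    out.feature_kind = "peak"
    out.obs = tiles.obs.copy()
    return out


def _peak_weight_matrix(tiles: CountsMatrix, peaks: PeakSet) -> sp.csr_matrix:
    from .qc import _parse_tile_coords

    chroms, starts, ends = _parse_tile_coords(tiles.features)
    rows, cols = [], []
    by_chrom = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        by_chrom[str(c)] = (idx, starts[idx], ends[idx])
    for pi, pk in enumerate(peaks):
        entry = by_chrom.get(pk.chrom)
        if entry is None:
            continue
        idx, st, en = entry
        lo = int(np.searchsorted(st, pk.start - (en[0] - st[0]), side="left"))
        hi = int(np.searchsorted(st, pk.end, side="left"))
        for j in range(lo, hi):
            if en[j] > pk.start and st[j] < pk.end:
                rows.append(int(idx[j]))
                cols.append(pi)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(tiles.n_features, len(peaks)),
    )


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

def _promoter_interval(g: GeneModel, window=(-2000, 100)) -> tuple[int, int]:
    lo, hi = window
    if g.strand == "+":
        return g.tss + lo, g.tss + hi
    return g.tss - hi + 1, g.tss - lo + 1


def annotate_peak(
    peak: GenomicInterval,
    gene_models: list[GeneModel],
    promoter_window=(-2000, 100),
    exons: dict | None = None,
) -> str:
    """Classify a peak: promoter > exonic > intronic > distal.

    The promoter window is strand-aware around the TSS. Without an exon
    table every gene body is treated as a single exonic-or-intronic region:
    a peak inside a body is ``intronic`` unless it overlaps an entry of
    ``exons`` (gene_id -> interval list), in which case ``exonic``.
    """
    in_body = False
    for g in gene_models:
        if g.body.chrom != peak.chrom:
            continue
        plo, phi = _promoter_interval(g, promoter_window)
        if peak.start < phi and plo < peak.end:
            return "promoter"
        if peak.start < g.body.end and g.body.start < peak.end:
            in_body = True
            if exons:
                for iv in exons.get(g.gene_id, []):
                    if peak.start < iv.end and iv.start < peak.end:
                        return "exonic"
    return "intronic" if in_body else "distal"


def annotate_peaks(
    peaks: PeakSet,
    gene_models: list[GeneModel],
    promoter_window=(-2000, 100),
    exons: dict | None = None,
) -> pd.Series:
    """Vectorized :func:`annotate_peak` over a PeakSet (id-indexed)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    out = {}
    for pk in peaks:
        out[pk.id] = annotate_peak(
            pk, by_chrom.get(pk.chrom, []), promoter_window, exons
        )
    return pd.Series(out, name="peak_class")


# ---------------------------------------------------------------------------
# Metacells
# ---------------------------------------------------------------------------

@dataclass
class MetacellGrouping:
    """Low-overlapping k-cell aggregates in a reduced space."""

    groups: list[np.ndarray]         # cell index arrays, each of size k
    k: int
    max_shared: int

    def __len__(self) -> int:
        return len(self.groups)

    def membership_matrix(self, n_cells: int) -> sp.csr_matrix:
        rows = np.repeat(np.arange(len(self.groups)), self.k)
        cols = np.concatenate(self.groups) if self.groups else np.array([], int)
        return sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(len(self.groups), n_cells)
        )


def make_metacells(
    reduced: ReducedSpace,
    k: int = 100,
    n_groups: int | None = None,
    max_shared: int | None = None,
    seed: int = 0,
) -> MetacellGrouping:
    """kNN metacells with a pairwise-overlap cap.

    Seed cells are chosen by farthest-point sampling (first seed fixed by
    ``seed``); each group is a seed's k nearest neighbors (including
    itself); candidate groups sharing more than ``max_shared`` cells with an
    accepted group are dropped, iterating until ``n_groups`` groups are
    accepted or candidates are exhausted.
    """
    emb = reduced.retained
    n = emb.shape[0]
    if k > n:
        raise ValueError(f"k={k} > n_cells={n}")
    if max_shared is None:
        max_shared = int(0.8 * k)
    if n_groups is None:
        n_groups = min(500, int(np.ceil(n / 20)))
    rng = np.random.default_rng(seed)
    # farthest-point sampling of candidate seeds (over-sample 2x for drops)
    n_seed = min(n, 2 * n_groups)
    first = int(rng.integers(n))
    seeds = [first]
    dist = np.linalg.norm(emb - emb[first], axis=1)
    for _ in range(n_seed - 1):
        nxt = int(dist.argmax())
        seeds.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(emb - emb[nxt], axis=1))
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, ind = nn.kneighbors(emb[seeds])
    groups: list[np.ndarray] = []
    member_sets: list[set] = []
    for row in ind:
        cand = set(row.tolist())
        if any(len(cand & m) > max_shared for m in member_sets):
            continue
        groups.append(np.sort(row))
        member_sets.append(cand)
        if len(groups) >= n_groups:
            break
    return MetacellGrouping(groups=groups, k=k, max_shared=max_shared)


def aggregate_metacells(
    counts, grouping: MetacellGrouping, lognorm: bool = True, scale: float = 1e4
) -> np.ndarray:
    """Sum features over each metacell; optionally depth-normalize + log.

    ``counts`` may be a CountsMatrix, sparse matrix or dense array of
    cells x features; result is metacells x features, dense.
    """
    X = counts.X if isinstance(counts, CountsMatrix) else counts
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    M = grouping.membership_matrix(X.shape[0])
    agg = np.asarray((M @ X).todense())
    if lognorm:
        totals = agg.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("metacell with zero total counts")
        agg = np.log1p(agg / totals * scale)
    return agg


def aggregate_metacell_means(values, grouping: MetacellGrouping) -> np.ndarray:
    """Plain group means (for already-normalized matrices, e.g. imputed
    expression)."""
    X = values.X if isinstance(values, CountsMatrix) else values
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    M = grouping.membership_matrix(X.shape[0]).multiply(1.0 / grouping.k)
    return np.asarray((M @ X).todense())


# ---------------------------------------------------------------------------
# Peak-to-gene correlation
# ---------------------------------------------------------------------------

def _candidate_pairs(peaks: PeakSet, gene_models: list[GeneModel], max_dist: int):
    """(peak_idx, gene_idx, signed distance) for same-chromosome pairs with
    |peak midpoint - TSS| <= max_dist."""
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order = np.argsort([g.tss for g in gene_models], kind="stable")
    genes_sorted = [gene_models[i] for i in order]
    gidx_sorted = np.asarray(order)
    chrom_arr = np.array([g.body.chrom for g in genes_sorted])
    tss_arr = np.array([g.tss for g in genes_sorted])
    for c in np.unique(chrom_arr):
        m = chrom_arr == c
        tss_by_chrom[str(c)] = (tss_arr[m], gidx_sorted[m])
    pi, gi, dist = [], [], []
    for i, pk in enumerate(peaks):
        entry = tss_by_chrom.get(pk.chrom)
        if entry is None:
            continue
        tss, gidx = entry
        mid = pk.midpoint
        lo = int(np.searchsorted(tss, mid - max_dist, side="left"))
        hi = int(np.searchsorted(tss, mid + max_dist, side="right"))
        for j in range(lo, hi):
            pi.append(i)
            gi.append(int(gidx[j]))
            dist.append(int(mid - tss[j]))
    return np.array(pi, int), np.array(gi, int), np.array(dist, int)


def correlate_peak_gene(
    atac_metacells: np.ndarray,
    rna_metacells: np.ndarray,
    peaks: PeakSet,
    gene_models: list[GeneModel],
    peak_classes: pd.Series | None = None,
    max_dist: int = 250_000,
) -> pd.DataFrame:
    """Pearson correlation of peak accessibility vs gene expression across
    metacells for every candidate cis pair.

    ``atac_metacells`` is metacells x peaks (aligned with ``peaks``),
    ``rna_metacells`` metacells x genes (aligned with ``gene_models``).
    p-values come from ``t = r * sqrt((n-2)/(1-r^2))`` with n = number of
    metacells; FDR is BH across all tested pairs. Zero-variance peaks or
    genes are skipped (and counted in ``df.attrs['n_skipped']``).
    """
    A = np.asarray(atac_metacells, float)
    G = np.asarray(rna_metacells, float)
    if A.shape[0] != G.shape[0]:
        raise ValueError("metacell row mismatch between modalities")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need >= 3 metacells")
    pi, gi, dist = _candidate_pairs(peaks, gene_models, max_dist)
    if peak_classes is None:
        peak_classes = annotate_peaks(peaks, gene_models)
    As = A - A.mean(axis=0)
    Gs = G - G.mean(axis=0)
    Asd = As.std(axis=0, ddof=1)
    Gsd = Gs.std(axis=0, ddof=1)
    valid = (Asd[pi] > 0) & (Gsd[gi] > 0)
    n_skipped = int((~valid).sum())
    pi, gi, dist = pi[valid], gi[valid], dist[valid]
    r = np.empty(pi.size)
    block = 50_000
    for lo in range(0, pi.size, block):
        hi = min(lo + block, pi.size)
        num = np.einsum(
            "ij,ij->j", As[:, pi[lo:hi]], Gs[:, gi[lo:hi]]
        ) / (n - 1)
        r[lo:hi] = num / (Asd[pi[lo:hi]] * Gsd[gi[lo:hi]])
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    from .differential import benjamini_hochberg

    fdr = benjamini_hochberg(p)
    peak_ids = np.array(peaks.ids)
    gene_ids = np.array([g.gene_id for g in gene_models])
    df = pd.DataFrame(
        {
            "peak_id": peak_ids[pi],
            "gene_id": gene_ids[gi],
            "r": r,
            "p": p,
            "fdr": fdr,
            "distance_bp": dist,
            "peak_class": peak_classes.loc[peak_ids[pi]].to_numpy(),
        }
    )
    df.attrs["n_skipped"] = n_skipped
    df.attrs["n_metacells"] = n
    return df


def filter_links(
    links: pd.DataFrame,
    r_min: float = 0.45,
    fdr_max: float = 1e-12,
    peak_class: str | None = "distal",
) -> pd.DataFrame:
    """The headline link set: ``r >= r_min`` and ``fdr <= fdr_max``,
    restricted to one peak class (distal by default)."""
    keep = (links["r"] >= r_min) & (links["fdr"] <= fdr_max)
    if peak_class is not None:
        keep &= links["peak_class"] == peak_class
    out = links.loc[keep].reset_index(drop=True)
    out.attrs["n_unique_peaks"] = int(out["peak_id"].nunique())
    out.attrs["n_links"] = int(len(out))
    return out


# ---------------------------------------------------------------------------
# k-means clustering of links
# ---------------------------------------------------------------------------

def kmeans_links(
    links: pd.DataFrame,
    peak_type_profiles: pd.DataFrame,
    gene_type_profiles: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Cluster links on concatenated row-scaled per-cell-type accessibility
    and expression profiles; label each cluster with its most-enriched cell
    type (argmax of the mean scaled profile).

    ``peak_type_profiles`` / ``gene_type_profiles`` are indexed by
    peak_id / gene_id with one column per cell type. Returns the link table
    with ``kmeans_cluster`` and ``cluster_celltype`` columns.
    """
    if links.empty:
        out = links.copy()
        out["kmeans_cluster"] = pd.Series(dtype=int)
        out["cluster_celltype"] = pd.Series(dtype=object)
        return out
    types = list(peak_type_profiles.columns)
    acc = peak_type_profiles.loc[links["peak_id"]].to_numpy(dtype=float)
    expr = gene_type_profiles.loc[links["gene_id"]].to_numpy(dtype=float)

    def row_scale(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    feats = np.hstack([row_scale(acc), row_scale(expr)])
    k_eff = min(k, feats.shape[0])
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=n_init).fit(feats)
    labels = km.labels_
    out = links.copy()
    out["kmeans_cluster"] = labels + 1            # 1-based cluster ids
    enrich = {}
    for c in range(k_eff):
        mean_prof = feats[labels == c].mean(axis=0)
        combined = mean_prof[: len(types)] + mean_prof[len(types):]
        enrich[c + 1] = types[int(np.argmax(combined))]
    out["cluster_celltype"] = out["kmeans_cluster"].map(enrich)
    out.attrs["cluster_celltype"] = enrich
    return out
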