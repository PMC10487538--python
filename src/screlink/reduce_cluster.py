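"""Dimensionality reduction, clustering and cross-modality integration.

RNA follows the standard single-cell recipe: depth-normalized log counts,
top-2000 variable genes by standardized variance ("vst"-style, with a
polynomial mean-variance trend), per-gene scaling with covariate regression,
PCA (30 of 50 components used downstream), shared-nearest-neighbor graph and
modularity clustering at resolution 0.8.

ATAC follows the tile-matrix recipe: TF-IDF weighting and two-round
iterative LSI on the most accessible / most variable tiles, dropping
components correlated with sequencing depth above 0.75. Cell-type labels
move from RNA to ATAC by projecting gene-activity scores into the RNA PCA
space and voting among k nearest reference cells; cells whose prediction
score is <= 0.5 are excluded downstream, mirroring the anchor-transfer
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .io_intervals import CountsMatrix, GeneModel

__all__ = [
    "ReducedSpace",
    "ClusterAssignment",
    "log_normalize",
    "select_hvg",
    "scale_and_regress",
    "pca",
    "tfidf",
    "iterative_lsi",
    "cluster_graph",
    "batch_center",
    "gene_activity",
    "RnaReference",
    "fit_rna_reference",
    "label_transfer",
    "marker_scores",
    "assign_cluster_celltypes",
    "filter_clusters",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ReducedSpace:
    """Cells x dims embedding with per-dimension depth diagnostics."""

    embedding: np.ndarray
    method: str                      # "pca" | "lsi"
    depth_correlation: np.ndarray
    retained_dims: np.ndarray
    barcodes: list[str] = field(default_factory=list)
    components: np.ndarray | None = None   # dims x features loadings
    feature_names: list[str] | None = None

    def __post_init__(self):
        if self.embedding.shape[1] > 50:
            raise ValueError("dims must be <= 50")

    @property
    def retained(self) -> np.ndarray:
        return self.embedding[:, self.retained_dims]

    def subset(self, mask) -> "ReducedSpace":
        idx = np.flatnonzero(np.asarray(mask))
        return ReducedSpace(
            self.embedding[idx], self.method, self.depth_correlation,
            self.retained_dims, [self.barcodes[i] for i in idx],
            self.components, self.feature_names,
        )


@dataclass
class ClusterAssignment:
    labels: np.ndarray               # cluster id per cell
    barcodes: list[str]
    resolution: float
    cluster_celltype: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")


# ---------------------------------------------------------------------------
# RNA normalization and feature selection
# ---------------------------------------------------------------------------

def downsample_counts(counts, target_depth: int, seed: int = 0) -> sp.csr_matrix:
    """Binomially thin each cell's counts to ``target_depth`` (cells already
    at or below the target are untouched).

    Equal-depth profiles have equal dropout rates, which removes the
    depth-dependence of log-normalized values — important wherever cells are
    *selected* (e.g. as transfer neighbors), since any selection bias toward
    deep cells otherwise turns into a systematic expression bias.
    """
    X = counts.X if isinstance(counts, CountsMatrix) else sp.csr_matrix(counts)
    X = sp.csr_matrix(X, dtype=np.int64, copy=True)
    rng = np.random.default_rng(seed)
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep_p = np.minimum(1.0, target_depth / np.maximum(totals, 1))
    p_per_entry = np.repeat(keep_p, np.diff(X.indptr))
    X.data = rng.binomial(X.data, p_per_entry)
    X.eliminate_zeros()
    return X


def log_normalize(counts, scale: float = 1e4):
    """``x' = ln(1 + scale * x / cell_total)``; zero-total cells are an error.

    Accepts a CountsMatrix or a sparse/dense array; returns a CSR matrix
    (zeros map to zeros, so sparsity is preserved).
    """
    X = counts.X if isinstance(counts, CountsMatrix) else sp.csr_matrix(counts)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError(f"{int((totals == 0).sum())} cells have zero total counts")
    X = sp.csr_matrix(X, dtype=np.float64, copy=True)
    inv = scale / totals
    X.data *= np.repeat(inv, np.diff(X.indptr))
    np.log1p(X.data, out=X.data)
    return X


def select_hvg(counts, n_top: int = 2000) -> np.ndarray:
    """Top variable genes by standardized variance.

    Per gene, raw counts are standardized with the expected standard
    deviation from a degree-2 polynomial fit of log10(variance) on
    log10(mean), clipped at sqrt(n_cells); genes are ranked by the variance
    of the clipped standardized values, ties broken by gene index. Returns
    selected gene indices in ascending order.
    """
    X = counts.X if isinstance(counts, CountsMatrix) else sp.csr_matrix(counts)
    n, m = X.shape
    if n_top > m:
        raise ValueError(f"n_top={n_top} exceeds n_genes={m}")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    usable = (mean > 0) & (var > 0)
    coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), deg=2)
    exp_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12))))
    exp_sd[~usable] = 1.0
    clip = np.sqrt(n)
    std_var = np.zeros(m)
    Xc = sp.csc_matrix(X)
    block = 512
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        dense = Xc[:, lo:hi].toarray()
        z = (dense - mean[lo:hi]) / exp_sd[lo:hi]
        np.clip(z, -clip, clip, out=z)
        std_var[lo:hi] = z.var(axis=0, ddof=1)
    std_var[~usable] = 0.0
    order = np.lexsort((np.arange(m), -std_var))
    return np.sort(order[:n_top])


def scale_and_regress(
    normalized, covariate: np.ndarray | None = None, clip: float = 10.0
) -> np.ndarray:
    """Per-gene least-squares residuals on the covariate, z-scored and
    clipped at +-``clip``. With no covariate this is plain centering and
    scaling. Returns a dense cells x genes array."""
    X = normalized.toarray() if sp.issparse(normalized) else np.array(normalized, dtype=float)
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        c = c - c.mean()
        denom = float(c @ c)
        if denom > 0:
            beta = (c @ X) / denom          # slope per gene
            X = X - np.outer(c, beta)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # residuals that vanish up to float noise must not be z-inflated
    tiny = sd <= 1e-10 * max(1.0, float(np.abs(X).max(initial=0.0)))
    X[:, tiny] = 0.0
    sd[tiny] = 1.0
    X = X / sd
    np.clip(X, -clip, clip, out=X)
    return X


# ---------------------------------------------------------------------------
# PCA / LSI
# ---------------------------------------------------------------------------

def _sign_fix(embedding: np.ndarray, components: np.ndarray):
    """Deterministic sign convention: the largest-magnitude loading of each
    component is positive."""
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return embedding * flip, components * flip[:, None]


def _depth_correlation(embedding: np.ndarray, depth: np.ndarray) -> np.ndarray:
    d = np.log10(np.maximum(np.asarray(depth, float), 1.0))
    d = d - d.mean()
    dn = np.linalg.norm(d)
    out = np.zeros(embedding.shape[1])
    if dn == 0:
        return out
    for j in range(embedding.shape[1]):
        e = embedding[:, j] - embedding[:, j].mean()
        en = np.linalg.norm(e)
        out[j] = float(e @ d / (en * dn)) if en > 0 else 0.0
    return out


def pca(
    scaled: np.ndarray,
    n_components: int = 50,
    depth: np.ndarray | None = None,
    barcodes: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> ReducedSpace:
    """Full-SVD PCA of the scaled matrix with a deterministic sign convention."""
    X = np.asarray(scaled, dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    emb = U[:, :k] * S[:k]
    comp = Vt[:k]
    emb, comp = _sign_fix(emb, comp)
    depth_corr = (
        _depth_correlation(emb, depth) if depth is not None else np.zeros(k)
    )
    return ReducedSpace(
        embedding=emb, method="pca", depth_correlation=depth_corr,
        retained_dims=np.arange(k), barcodes=list(barcodes or []),
        components=comp, feature_names=list(feature_names or []) or None,
    )


def tfidf(tiles, scale: float = 1e4, binarize: bool = True) -> sp.csr_matrix:
    """``log(1 + tf * idf * scale)`` with ``tf = count / cell_total`` and
    ``idf = n_cells / n_cells_with_feature``."""
    X = tiles.X if isinstance(tiles, CountsMatrix) else sp.csr_matrix(tiles)
    X = sp.csr_matrix(X, dtype=np.float64, copy=True)
    if binarize:
        X.data = np.ones_like(X.data)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    n_cells = X.shape[0]
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = n_cells / np.maximum(df, 1.0)
    X.data *= np.repeat(1.0 / totals, np.diff(X.indptr))
    X = sp.csr_matrix(X @ sp.diags(idf))
    X.data = np.log1p(X.data * scale)
    return X


def _svd_reduce(mat: sp.csr_matrix, dims: int, seed: int):
    svd = TruncatedSVD(n_components=dims, random_state=seed, algorithm="randomized")
    emb = svd.fit_transform(mat)
    emb, comp = _sign_fix(emb, svd.components_)
    return emb, comp


def iterative_lsi(
    tiles: CountsMatrix,
    n_var: int = 25_000,
    n_iter: int = 2,
    dims: int = 30,
    cor_cutoff: float = 0.75,
    seed: int = 0,
    binarize: bool = True,
    n_coarse_clusters: int = 8,
) -> ReducedSpace:
    """Two-round TF-IDF + truncated SVD on variable tiles.

    Round 1 uses the ``n_var`` most accessible tiles and produces coarse
    k-means clusters; later rounds re-select the ``n_var`` tiles most
    variable across the coarse-cluster pseudobulk profiles. Components whose
    absolute correlation with log10 depth exceeds ``cor_cutoff`` are dropped
    from ``retained_dims``.
    """
    X = tiles.X
    depth = np.asarray(X.sum(axis=1)).ravel()
    n_tiles = X.shape[1]
    if n_var > n_tiles:
        warnings.warn(
            f"n_var={n_var} exceeds {n_tiles} tiles; using all tiles",
            stacklevel=2,
        )
        n_var = n_tiles
    accessibility = np.asarray((X > 0).sum(axis=0)).ravel()
    order = np.lexsort((np.arange(n_tiles), -accessibility))
    var_idx = np.sort(order[:n_var])
    emb_full = comp = emb = None
    for it in range(max(n_iter, 1)):
        if it > 0:
            clusters = KMeans(
                n_clusters=min(n_coarse_clusters, emb.shape[0]),
                random_state=seed, n_init=10,
            ).fit_predict(emb)
            prof = np.zeros((clusters.max() + 1, n_tiles))
            for c in range(clusters.max() + 1):
                rows = np.flatnonzero(clusters == c)
                sub = np.asarray(X[rows].sum(axis=0)).ravel()
                prof[c] = np.log1p(sub / max(sub.sum(), 1) * 1e4)
            tile_var = prof.var(axis=0)
            order = np.lexsort((np.arange(n_tiles), -tile_var))
            var_idx = np.sort(order[:n_var])
        mat = tfidf(X[:, var_idx], binarize=binarize)
        emb_full, comp = _svd_reduce(mat, dims, seed)
        corr = _depth_correlation(emb_full, depth)
        retained = np.flatnonzero(np.abs(corr) <= cor_cutoff)
        emb = emb_full[:, retained]
    return ReducedSpace(
        embedding=emb_full, method="lsi", depth_correlation=corr,
        retained_dims=retained, barcodes=list(tiles.barcodes),
        components=comp,
        feature_names=[tiles.features[i] for i in var_idx],
    )


# ---------------------------------------------------------------------------
# Graph clustering and batch centering
# ---------------------------------------------------------------------------

def cluster_graph(
    reduced: ReducedSpace,
    k_nn: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> ClusterAssignment:
    """Shared-nearest-neighbor graph + modularity community detection.

    Edges are Jaccard overlaps of k-NN neighborhoods; communities come from
    the RB-configuration (modularity with resolution) partition, seeded.
    """
    emb = reduced.retained
    n = emb.shape[0]
    k = min(k_nn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, ind = nn.kneighbors(emb)
    ind = ind[:, 1:]
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, ind.ravel())), shape=(n, n))
    shared = (adj @ adj.T).tocoo()
    union = 2 * k - shared.data
    jacc = shared.data / union
    keep = (jacc > 1.0 / 15.0) & (shared.row < shared.col)
    g = ig.Graph(
        n=n,
        edges=list(zip(shared.row[keep].tolist(), shared.col[keep].tolist())),
        edge_attrs={"weight": jacc[keep].tolist()},
        directed=False,
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.array(part.membership)
    return ClusterAssignment(labels, list(reduced.barcodes), resolution)


def batch_center(reduced: ReducedSpace, batches) -> ReducedSpace:
    """Subtract per-batch means in the reduced space, restoring the global
    mean — a deliberately simple stand-in for heavier batch integration."""
    emb = reduced.embedding.copy()
    b = np.asarray(batches)
    global_mean = emb.mean(axis=0)
    for batch in np.unique(b):
        rows = b == batch
        emb[rows] += global_mean - emb[rows].mean(axis=0)
    return ReducedSpace(
        emb, reduced.method, reduced.depth_correlation, reduced.retained_dims,
        list(reduced.barcodes), reduced.components, reduced.feature_names,
    )


# ---------------------------------------------------------------------------
# Gene activity
# ---------------------------------------------------------------------------

def gene_activity(
    atac: CountsMatrix,
    gene_models: list[GeneModel],
    promoter_ext: int = 2000,
    decay_bp: float = 5000.0,
) -> CountsMatrix:
    """Per-gene accessibility scores from the tile matrix.

    A tile overlapping the gene body contributes its counts with weight 1; a
    tile in the strand-aware promoter extension contributes with weight
    ``exp(-distance_to_body / decay_bp)``. Returns a cells x genes container
    of float scores.
    """
    from .qc import _parse_tile_coords

    chroms, starts, ends = _parse_tile_coords(atac.features)
    w_rows, w_cols, w_vals = [], [], []
    by_chrom = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        by_chrom[c] = (idx, starts[idx])
    for gi, g in enumerate(gene_models):
        entry = by_chrom.get(g.body.chrom)
        if entry is None:
            continue
        idx, st = entry
        width = int(ends[idx[0]] - st[0])
        if g.strand == "+":
            lo, hi = g.body.start - promoter_ext, g.body.end
        else:
            lo, hi = g.body.start, g.body.end + promoter_ext
        first = int(np.searchsorted(st, lo - width, side="left"))
        last = int(np.searchsorted(st, hi, side="left"))
        for j in range(first, last):
            t_start = int(st[j])
            t_end = t_start + width
            if t_end <= lo or t_start >= hi:
                continue
            if t_end > g.body.start and t_start < g.body.end:
                w = 1.0
            else:
                d = g.body.start - t_end if t_end <= g.body.start else t_start - g.body.end
                w = float(np.exp(-max(d, 0) / decay_bp))
            w_rows.append(gi)
            w_cols.append(idx[j])
            w_vals.append(w)
    W = sp.csr_matrix(
        (w_vals, (w_rows, w_cols)), shape=(len(gene_models), atac.n_features)
    )
    scores = sp.csr_matrix(atac.X @ W.T, dtype=np.float64)
    out = CountsMatrix.__new__(CountsMatrix)
    out.X = scores
    out.barcodes = list(atac.barcodes)
    out.features = [g.gene_id for g in gene_models]
    out.feature_kind = "gene"
    out.obs = atac.obs.copy()
    return out


# ---------------------------------------------------------------------------
# Label transfer
# ---------------------------------------------------------------------------

@dataclass
class RnaReference:
    """Frozen RNA reference for projection-based label transfer."""

    lognorm: sp.csr_matrix          # cells x genes, all genes
    genes: list[str]
    hvg_idx: np.ndarray
    components: np.ndarray          # dims x HVG loadings
    embedding: np.ndarray           # cells x dims
    labels: np.ndarray
    samples: np.ndarray
    barcodes: list[str]


def fit_rna_reference(
    rna: CountsMatrix,
    labels,
    n_hvg: int = 2000,
    n_components: int = 30,
    covariate: np.ndarray | None = None,
) -> RnaReference:
    """Log-normalize, select HVGs, scale, and fit the reference PCA."""
    ln = log_normalize(rna)
    hvg = select_hvg(rna, n_top=min(n_hvg, rna.n_features))
    scaled = scale_and_regress(ln[:, hvg].toarray(), covariate=covariate)
    space = pca(scaled, n_components=n_components, depth=rna.cell_totals(),
                barcodes=rna.barcodes)
    return RnaReference(
        lognorm=ln, genes=list(rna.features), hvg_idx=hvg,
        components=space.components, embedding=space.embedding,
        labels=np.asarray(labels),
        samples=rna.obs["sample"].to_numpy()
        if "sample" in rna.obs
        else np.array(["_"] * rna.n_cells),
        barcodes=list(rna.barcodes),
    )


def label_transfer(
    ref: RnaReference,
    query_activity: CountsMatrix,
    k: int = 15,
    min_score: float = 0.5,
    constrain_by_sample: bool = False,
    impute_k: int | None = None,
    align_centroids: bool = True,
):
    """Assign reference labels to query cells via projection + kNN voting.

    The query gene-activity matrix is log-normalized, restricted to the
    reference HVGs (missing genes contribute zero), z-scored per gene with
    its own statistics, and projected with the reference loadings. Each
    query cell takes the majority label among its k nearest reference cells
    (restricted to cells of the same sample when constrained); the
    prediction score is the neighbor fraction of the winning label, and the
    imputed expression is the uniform mean of the ``impute_k`` nearest
    neighbors' normalized expression (``impute_k`` defaults to ``k``; a
    small value preserves reference-cell diversity instead of collapsing
    every query cell of a type onto the same pool mean). Cells with score
    <= ``min_score`` are flagged excluded.

    With ``align_centroids`` (default), a first neighbor pass produces
    provisional labels, the query projections are shifted so that each
    provisional (label, sample) centroid coincides with the corresponding
    reference centroid, and neighbors are recomputed. This removes the
    systematic within-cluster offset of the raw projection, which would
    otherwise bias every imputed gene by its loading along the offset
    direction.

    Returns ``(table, imputed)``: table has columns label, prediction_score,
    excluded; imputed is cells x reference-genes (CSR).
    """
    act_ln = log_normalize(query_activity)
    gene_pos = {g: i for i, g in enumerate(query_activity.features)}
    hvg_genes = [ref.genes[i] for i in ref.hvg_idx]
    cols = np.array([gene_pos.get(g, -1) for g in hvg_genes])
    n_q = query_activity.n_cells
    dense = np.zeros((n_q, len(hvg_genes)))
    have = cols >= 0
    dense[:, have] = act_ln[:, cols[have]].toarray()
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    proj = ((dense - mu) / sd) @ ref.components.T

    q_samples = (
        query_activity.obs["sample"].to_numpy()
        if "sample" in query_activity.obs
        else np.array(["_"] * n_q)
    )
    groups = (
        {s: np.flatnonzero(ref.samples == s) for s in np.unique(q_samples)}
        if constrain_by_sample
        else {None: np.arange(len(ref.barcodes))}
    )
    for key, ridx in groups.items():
        if ridx.size == 0:
            raise ValueError(f"no reference cells for sample {key!r}")
        if ridx.size < k:
            raise ValueError(f"fewer reference cells ({ridx.size}) than k={k}")

    def neighbor_pass(projection):
        nbr = np.zeros((n_q, k), dtype=np.int64)
        for key, ridx in groups.items():
            nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(
                ref.embedding[ridx]
            )
            rows = (
                np.flatnonzero(q_samples == key)
                if constrain_by_sample
                else np.arange(n_q)
            )
            if rows.size == 0:
                continue
            _, ind = nn.kneighbors(projection[rows])
            nbr[rows] = ridx[ind]
        return nbr

    def vote(nbr):
        lab = np.empty(n_q, dtype=object)
        sc = np.zeros(n_q)
        for i in range(n_q):
            vals, counts = np.unique(ref.labels[nbr[i]], return_counts=True)
            j = np.lexsort((vals, -counts))[0]
            lab[i] = vals[j]
            sc[i] = counts[j] / k
        return lab, sc

    neighbor_idx = neighbor_pass(proj)
    labels_out, scores = vote(neighbor_idx)
    if align_centroids:
        proj = proj.copy()
        for key, ridx in groups.items():
            q_rows = (
                np.flatnonzero(q_samples == key)
                if constrain_by_sample
                else np.arange(n_q)
            )
            for lab in np.unique(ref.labels[ridx]):
                r_sub = ridx[ref.labels[ridx] == lab]
                q_sub = q_rows[labels_out[q_rows] == lab]
                if r_sub.size < 3 or q_sub.size < 3:
                    continue
                proj[q_sub] += ref.embedding[r_sub].mean(axis=0) - proj[q_sub].mean(axis=0)
        neighbor_idx = neighbor_pass(proj)
        labels_out, scores = vote(neighbor_idx)
    # Imputation neighbors: local but usage-balanced. Unconstrained nearest
    # neighbors concentrate on a few hub reference cells (some cells get
    # used hundreds of times, a quarter never); any chance covariance
    # between that frozen usage pattern and a gene's values then becomes a
    # systematic per-cell-type expression bias in the imputed matrix. A cap
    # on per-reference-cell reuse keeps usage nearly uniform over the pool
    # while preserving locality.
    ik = min(impute_k or k, k)
    impute_idx = np.zeros((n_q, ik), dtype=np.int64)
    for key, ridx in groups.items():
        rows = (
            np.flatnonzero(q_samples == key)
            if constrain_by_sample
            else np.arange(n_q)
        )
        if rows.size == 0:
            continue
        cand_k = int(min(ridx.size, max(16 * ik, 64)))
        nn = NearestNeighbors(n_neighbors=cand_k, metric="cosine").fit(
            ref.embedding[ridx]
        )
        _, cand = nn.kneighbors(proj[rows])
        cap = max(1, int(np.ceil(rows.size * ik / ridx.size)))
        used = np.zeros(ridx.size, dtype=np.int64)
        for qi, r in enumerate(rows):
            chosen = []
            for c in cand[qi]:
                if used[c] < cap:
                    chosen.append(c)
                    used[c] += 1
                    if len(chosen) == ik:
                        break
            while len(chosen) < ik:      # candidates exhausted: least-used cell
                c = int(used.argmin())
                chosen.append(c)
                used[c] += 1
            impute_idx[r] = ridx[np.array(chosen)]
    rows = np.repeat(np.arange(n_q), ik)
    P = sp.csr_matrix(
        (np.full(n_q * ik, 1.0 / ik), (rows, impute_idx.ravel())),
        shape=(n_q, len(ref.barcodes)),
    )
    imputed = sp.csr_matrix(P @ ref.lognorm)
    table = pd.DataFrame(
        {
            "label": labels_out,
            "prediction_score": scores,
            "excluded": scores <= min_score,
        },
        index=pd.Index(query_activity.barcodes, name="barcode"),
    )
    table.attrs["neighbor_idx"] = neighbor_idx
    return table, imputed


# ---------------------------------------------------------------------------
# Cluster labeling and filtering
# ---------------------------------------------------------------------------

def marker_scores(lognorm, genes: list[str], marker_genes: dict) -> pd.DataFrame:
    """Mean normalized expression of each type's marker list per cell."""
    pos = {g: i for i, g in enumerate(genes)}
    out = {}
    for ctype, markers in marker_genes.items():
        cols = [pos[g] for g in markers if g in pos]
        if not cols:
            raise ValueError(f"no marker genes of {ctype!r} present")
        out[ctype] = np.asarray(lognorm[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(out)


def assign_cluster_celltypes(
    assignment: ClusterAssignment, cell_labels
) -> ClusterAssignment:
    """Majority vote of per-cell labels within each cluster (ties broken
    lexicographically)."""
    labels = np.asarray(cell_labels)
    mapping = {}
    for c in range(assignment.n_clusters):
        sub = labels[assignment.labels == c]
        vals, counts = np.unique(sub, return_counts=True)
        mapping[c] = vals[np.lexsort((vals, -counts))[0]]
    assignment.cluster_celltype = mapping
    return assignment


def filter_clusters(
    assignment: ClusterAssignment,
    mean_counts: np.ndarray,
    mean_min: float = 5000.0,
    drop_labels: set | None = None,
):
    """Drop clusters whose mean per-cell counts fall below ``mean_min`` or
    whose cell-type label is in ``drop_labels``. Returns (kept cluster ids,
    per-cell keep mask)."""
    drop_labels = drop_labels if drop_labels is not None else {"unassigned"}
    counts = np.asarray(mean_counts, float)
    kept = []
    for c in range(assignment.n_clusters):
        rows = assignment.labels == c
        if counts[rows].mean() < mean_min:
            continue
        if assignment.cluster_celltype.get(c) in drop_labels:
            continue
        kept.append(c)
    mask = np.isin(assignment.labels, kept)
    return kept, mask
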