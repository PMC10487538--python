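"""Per-cell quality control for both modalities.

RNA cells are filtered on UMI depth, genes detected and mitochondrial
fraction (outliers defined by strict inequalities, so boundary cells are
retained). ATAC cells are filtered on a Gaussian-mixture depth threshold and
a tile-based TSS-enrichment proxy. Doublets are scored by the fraction of
simulated doublets (averaged random cell pairs) among each cell's nearest
neighbors in a reduced space, with a removal budget proportional to the
expected doublet count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .io_intervals import CountsMatrix, GeneModel

__all__ = [
    "rna_qc_filter",
    "gmm_depth_threshold",
    "tss_scores",
    "tss_filter",
    "simulate_doublets",
    "doublet_scores",
    "remove_top_doublets",
]


# ---------------------------------------------------------------------------
# RNA QC
# ---------------------------------------------------------------------------

def rna_qc_filter(
    rna: CountsMatrix,
    umi_min: int = 5000,
    genes_min: int = 2000,
    mito_max: float = 25.0,
    mito_prefix: str = "MT-",
):
    """Remove outlier cells: ``umi < umi_min`` OR ``genes < genes_min`` OR
    ``pct_mito > mito_max``. Boundary values are retained.

    Returns ``(kept CountsMatrix, CellQc table)``; the table covers all input
    cells with per-criterion flags and a ``keep`` column. Raises if no cell
    survives, reporting per-criterion removal counts.
    """
    umi = rna.cell_totals()
    n_genes = np.asarray((rna.X > 0).sum(axis=1)).ravel()
    mito_cols = np.array([f.startswith(mito_prefix) for f in rna.features])
    if mito_cols.any():
        mito_counts = np.asarray(rna.X[:, mito_cols].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(rna.n_cells)
    pct_mito = np.where(umi > 0, 100.0 * mito_counts / np.maximum(umi, 1), 0.0)
    fail_umi = umi < umi_min
    fail_genes = n_genes < genes_min
    fail_mito = pct_mito > mito_max
    keep = ~(fail_umi | fail_genes | fail_mito)
    qc = pd.DataFrame(
        {
            "umi_count": umi.astype(int),
            "n_genes_expressed": n_genes.astype(int),
            "pct_mito": pct_mito,
            "fail_umi": fail_umi,
            "fail_genes": fail_genes,
            "fail_mito": fail_mito,
            "keep": keep,
        },
        index=pd.Index(rna.barcodes, name="barcode"),
    )
    if not keep.any():
        raise ValueError(
            "no cells survive RNA QC "
            f"(umi<{umi_min}: {int(fail_umi.sum())}, "
            f"genes<{genes_min}: {int(fail_genes.sum())}, "
            f"mito>{mito_max}: {int(fail_mito.sum())})"
        )
    return rna.subset_cells(keep), qc


# ---------------------------------------------------------------------------
# ATAC depth threshold
# ---------------------------------------------------------------------------

def gmm_depth_threshold(
    log10_fragments: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    min_weight: float = 0.05,
    fallback_floor: float = 3.0,
) -> float:
    """Depth cutoff from a 2-component 1-D Gaussian mixture.

    The cutoff is the point between the two component means where the
    posterior responsibility flips. A degenerate fit — either component
    weight below ``min_weight``, or components separated by less than two
    pooled standard deviations (one cluster split in half) — falls back to
    ``fallback_floor``.
    """
    x = np.asarray(log10_fragments, dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in log10_fragments")
    gm = GaussianMixture(
        n_components=2, n_init=n_restarts, random_state=seed, covariance_type="full"
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    lo, hi = means[order]
    w = gm.weights_[order]
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    if w.min() < min_weight or (hi - lo) < 2.0 * pooled_sd:
        return float(fallback_floor)
    grid = np.linspace(lo, hi, 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))[:, order[1]]
    crossing = np.flatnonzero(post >= 0.5)
    if crossing.size == 0:
        return float(fallback_floor)
    return float(grid[crossing[0]])


# ---------------------------------------------------------------------------
# TSS enrichment proxy (tile-based)
# ---------------------------------------------------------------------------

def _parse_tile_coords(features: list[str]):
    chroms, starts, ends = [], [], []
    for f in features:
        chrom, rest = f.rsplit(":", 1)
        a, b = rest.split("-")
        chroms.append(chrom)
        starts.append(int(a))
        ends.append(int(b))
    return np.array(chroms), np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _tss_tile_sets(features: list[str], gene_models: list[GeneModel]):
    chroms, starts, ends = _parse_tile_coords(features)
    width = int(np.median(ends - starts))
    index = {(c, int(s)): i for i, (c, s) in enumerate(zip(chroms, starts))}
    tss_idx, flank_idx = set(), set()
    for g in gene_models:
        c = g.body.chrom
        t0 = (g.tss // width) * width
        for d in (-1, 0, 1):
            j = index.get((c, t0 + d * width))
            if j is not None:
                tss_idx.add(j)
        for d in (-4, -3, -2, 2, 3, 4):
            j = index.get((c, t0 + d * width))
            if j is not None:
                flank_idx.add(j)
    flank_idx -= tss_idx
    return np.array(sorted(tss_idx)), np.array(sorted(flank_idx))


def tss_scores(
    atac: CountsMatrix,
    gene_models: list[GeneModel],
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Per-cell TSS enrichment: mean counts in tiles overlapping a TSS +- 1
    tile over mean counts in flanking tiles (offsets 2-4 tiles), with a
    pseudocount in the denominator."""
    tss_idx, flank_idx = _tss_tile_sets(atac.features, gene_models)
    if tss_idx.size == 0:
        raise ValueError("no TSS-overlapping tiles found in the tile matrix")
    tss_mean = np.asarray(atac.X[:, tss_idx].mean(axis=1)).ravel()
    flank_mean = np.asarray(atac.X[:, flank_idx].mean(axis=1)).ravel()
    return tss_mean / (flank_mean + pseudocount)


def tss_filter(
    atac: CountsMatrix,
    gene_models: list[GeneModel],
    threshold_log10: float = 0.9,
    pseudocount: float = 0.01,
):
    """Keep cells with ``log10(tss_score + 1) >= threshold_log10``."""
    score = tss_scores(atac, gene_models, pseudocount=pseudocount)
    keep = np.log10(score + 1.0) >= threshold_log10
    return atac.subset_cells(keep), score, keep


# ---------------------------------------------------------------------------
# Doublet scoring
# ---------------------------------------------------------------------------

def simulate_doublets(counts: CountsMatrix, n_sim: int, seed: int) -> sp.csr_matrix:
    """Averaged random cell pairs (rounded down), the synthetic doublets."""
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    i = rng.integers(0, n, size=n_sim)
    j = rng.integers(0, n, size=n_sim)
    bump = rng.integers(1, n, size=n_sim)
    j = np.where(j == i, (i + bump) % n, j)
    sim = (counts.X[i] + counts.X[j]).multiply(0.5)
    sim.data = np.floor(sim.data)
    sim.eliminate_zeros()
    return sp.csr_matrix(sim)


def doublet_scores(
    counts: CountsMatrix,
    reducer,
    n_sim: int | None = None,
    k: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of simulated doublets among the k nearest neighbors of each
    observed cell, in a reduced space computed on observed + simulated cells.

    ``reducer`` maps a (cells + doublets) x features count matrix to an
    embedding array; it is applied to the union so observed cells and
    simulated doublets share one space.
    """
    n = counts.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    if n_sim is None:
        n_sim = n
    sim = simulate_doublets(counts, n_sim, seed)
    union = sp.vstack([counts.X, sim], format="csr")
    emb = np.asarray(reducer(union))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, ind = nn.kneighbors(emb[:n])
    ind = ind[:, 1:]  # drop self
    return (ind >= n).mean(axis=1)


def remove_top_doublets(
    counts: CountsMatrix,
    scores: np.ndarray,
    expected_rate_per_1000: float = 8.0,
    filter_ratio: float = 1.0,
):
    """Remove the ``filter_ratio x expected`` highest-scoring cells, where
    the expected doublet count scales with cell number squared (rate per
    1,000 cells times n/1000 times n), capped at n. Deterministic: ties are
    broken by barcode order."""
    n = counts.n_cells
    expected = expected_rate_per_1000 * (n / 1000.0) * n / 1000.0
    n_remove = int(min(n, round(filter_ratio * expected)))
    if n_remove <= 0:
        return counts, np.zeros(n, dtype=bool)
    order = np.lexsort((np.arange(n), -np.asarray(scores)))
    remove = np.zeros(n, dtype=bool)
    remove[order[:n_remove]] = True
    return counts.subset_cells(~remove), remove
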