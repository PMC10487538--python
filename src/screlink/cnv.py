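"""Copy-number inference from scRNA expression and malignancy calling.

The residual profile is computed the way expression-based CNV callers do it:
genes are ordered along the genome, lowly expressed genes dropped, per-gene
log expression centered on the mean of designated reference cells (immune and
endothelial populations), smoothed with a moving average over neighboring
genes within each chromosome, re-centered per cell by its median, and
denoised by shrinking residuals inside a reference-derived noise band to
zero.

Malignancy calls follow the two-axis procedure: each cell gets a CNV score
(mean squared residual) and a correlation with the mean profile of the top
5% highest-scoring cells; cells high on both axes are called tumor, cells
low on both normal, everything else unassigned. The two cutoffs are this
package's own (the score cutoff is a quantile of the reference-cell scores,
the correlation cutoff a fixed value), both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_intervals import GeneModel

__all__ = ["CnvProfile", "infer_cnv", "classify_malignant"]


@dataclass
class CnvProfile:
    """Cells x genome-ordered-window residual matrix with per-cell scores."""

    residuals: np.ndarray            # cells x windows (gene-centered windows)
    window_genes: list[str]          # gene id per window center
    window_chrom: np.ndarray
    barcodes: list[str]
    reference_mask: np.ndarray       # True for reference cells
    cnv_score: np.ndarray | None = None
    cnv_correlation: np.ndarray | None = None
    call: np.ndarray | None = None


def _genome_order(gene_models: list[GeneModel], gene_ids: list[str]):
    pos = {g.gene_id: g for g in gene_models}
    present = [g for g in gene_ids if g in pos]
    present.sort(key=lambda g: (pos[g].body.chrom, pos[g].body.start, g))
    return present, np.array([pos[g].body.chrom for g in present])


def _moving_average_rows(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with truncated edge windows."""
    n = X.shape[1]
    half = window // 2
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv(
    lognorm,
    genes: list[str],
    gene_models: list[GeneModel],
    reference_mask,
    barcodes: list[str],
    expr_cutoff: float = 0.1,
    window: int = 101,
    denoise_sd: float = 1.5,
    run_window: int = 150,
    exclude_prefix: str = "MT-",
) -> CnvProfile:
    """Reference-centered, genome-smoothed expression residuals.

    ``lognorm`` is the cells x genes normalized log expression;
    ``reference_mask`` flags the cells whose mean defines the neutral
    baseline. Genes with mean normalized expression below ``expr_cutoff``,
    genes without a model, and genes on ``exclude_prefix`` contigs are
    dropped. ``window`` must be odd; chromosomes shorter than the window use
    truncated windows.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference group is empty")
    X = lognorm.toarray() if sp.issparse(lognorm) else np.asarray(lognorm, float)
    mean_expr = X.mean(axis=0)
    gene_pos = {g: i for i, g in enumerate(genes)}
    expressed = [
        g for g in genes
        if mean_expr[gene_pos[g]] >= expr_cutoff and not g.startswith(exclude_prefix)
    ]
    ordered, chroms = _genome_order(gene_models, expressed)
    if not ordered:
        raise ValueError("no expressed genes with gene models")
    cols = np.array([gene_pos[g] for g in ordered])
    E = X[:, cols]
    # center on the reference mean per gene
    E = E - E[reference_mask].mean(axis=0)
    # genome smoothing within chromosomes
    smooth = np.empty_like(E)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        if idx.size < window:
            pass  # truncated windows handle short chromosomes
        smooth[:, idx] = _moving_average_rows(E[:, idx], window)
    # per-cell, per-chromosome re-centering by the median: a cell type's
    # expression-program load differs between chromosomes (a compositional
    # offset), which would masquerade as a whole-chromosome CNV; centering
    # each chromosome keeps sub-chromosomal runs detectable while removing
    # the plateau (whole-chromosome events are invisible to this variant)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        smooth[:, idx] -= np.median(smooth[:, idx], axis=1, keepdims=True)
    # denoise: shrink residuals inside the reference noise band to zero
    ref_sd = smooth[reference_mask].std()
    band = denoise_sd * ref_sd
    denoised = np.where(np.abs(smooth) <= band, 0.0, smooth)
    profile = CnvProfile(
        residuals=denoised,
        window_genes=ordered,
        window_chrom=chroms,
        barcodes=list(barcodes),
        reference_mask=reference_mask,
    )
    # CNV burden score: a studentized run-scale matched filter. Copy-number
    # events are *contiguous* runs of genes, while cell-type expression
    # programs are scattered across the genome, so the running mean of the
    # centered residuals over ~run_window genome-ordered genes concentrates
    # CNV signal but averages program noise away. Dividing by the cell's
    # own residual scale makes the statistic comparable across cells of
    # different depth and program load; the score is the largest absolute
    # studentized running mean anywhere in the genome.
    centered_parts = []
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        cen = E[:, idx] - np.median(E[:, idx], axis=1, keepdims=True)
        centered_parts.append(cen)
    allcen = np.concatenate(centered_parts, axis=1)
    # outlier genes (marker programs, bursty genes: |residual| > 3 robust
    # SDs for that cell) are dropped from the filter — a copy-number run is
    # a small *consistent* shift across every background gene in the run,
    # so removing sparse large deviations sharpens it
    mad = np.median(np.abs(allcen), axis=1) * 1.4826
    mad[mad == 0] = 1.0
    clip = (3.0 * mad)[:, None]
    keep_all = np.abs(allcen) < clip
    masked = np.where(keep_all, allcen, 0.0)
    denom = keep_all.sum(axis=1)
    cell_sd = np.sqrt(
        (masked**2).sum(axis=1) / np.maximum(denom - 1, 1)
    )
    cell_sd[cell_sd == 0] = 1.0
    score = np.zeros(E.shape[0])

    def movsum(M, w):
        half = w // 2
        n = M.shape[1]
        cs = np.concatenate([np.zeros((M.shape[0], 1)), np.cumsum(M, axis=1)], axis=1)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        return cs[:, hi] - cs[:, lo]

    for cen in centered_parts:
        keep = np.abs(cen) < clip
        num = movsum(np.where(keep, cen, 0.0), run_window)
        cnt = movsum(keep.astype(float), run_window)
        cnt_safe = np.maximum(cnt, 1.0)
        z = np.abs(num / cnt_safe) * np.sqrt(cnt_safe) / cell_sd[:, None]
        score = np.maximum(score, z.max(axis=1))
    profile.cnv_score = score
    return profile


def classify_malignant(
    profile: CnvProfile,
    top_pct: float = 0.05,
    score_quantile: float = 0.75,
    outlier_mult: float = 3.0,
    corr_min: float = 0.4,
    corr_strong: float = 0.7,
    tier2_frac: float = 0.8,
    min_tumor_cells: int = 20,
    clusters: np.ndarray | None = None,
    cluster_disagreement: float = 0.30,
) -> pd.DataFrame:
    """Three-way malignancy call from (cnv_score, cnv_correlation).

    The top ``top_pct`` cells by CNV score define a putative-tumor mean
    profile. The tumor score cutoff is an outlier fence over the reference
    cells' scores: ``ref_median + outlier_mult * (ref_quantile(score_quantile)
    - ref_median)``. A cell is ``tumor`` if its score exceeds the fence AND
    its correlation with the putative-tumor profile exceeds ``corr_min``;
    ``normal`` if at or below the reference median score with correlation at
    or below ``corr_min``; otherwise ``unassigned``. Reference cells anchor
    the baseline and are never called tumor.

    A plain reference quantile (without the fence multiplier) cannot give a
    clean CNV-free null — by construction a fixed fraction of CNV-free cells
    exceeds any within-distribution quantile — so the fence is calibrated as
    a far-outlier rule instead.

    With ``clusters`` given, a per-cluster majority call is added; clusters
    whose cells disagree with the majority more than ``cluster_disagreement``
    become ``unassigned``.
    """
    R = profile.residuals
    n = R.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 cells for a stable top slice, got {n}")
    score = (
        profile.cnv_score if profile.cnv_score is not None else (R**2).mean(axis=1)
    )
    n_top = max(1, int(round(top_pct * n)))
    top_idx = np.lexsort((np.arange(n), -score))[:n_top]
    top_profile = R[top_idx].mean(axis=0)
    tp = top_profile - top_profile.mean()
    tp_norm = np.linalg.norm(tp)
    corr = np.zeros(n)
    if tp_norm > 0:
        Rc = R - R.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Rc, axis=1)
        ok = norms > 0
        corr[ok] = (Rc[ok] @ tp) / (norms[ok] * tp_norm)
    ref_scores = score[profile.reference_mask]
    ref_med = float(np.median(ref_scores))
    ref_hi = float(np.quantile(ref_scores, score_quantile))
    score_hi = ref_med + outlier_mult * max(ref_hi - ref_med, 0.0)
    score_med = ref_med
    call = np.full(n, "unassigned", dtype=object)
    # two-tier gate: over the fence with moderate correlation, or slightly
    # below it with strong correlation to the putative-tumor profile
    passers = ((score > score_hi) & (corr > corr_min)) | (
        (score > tier2_frac * score_hi) & (corr > corr_strong)
    )
    # a handful of isolated fence-passers is noise, not a tumor population
    if passers.sum() >= min_tumor_cells:
        call[passers] = "tumor"
    call[(score <= score_med) & (corr <= corr_min)] = "normal"
    call[profile.reference_mask] = np.where(
        call[profile.reference_mask] == "tumor", "unassigned",
        call[profile.reference_mask],
    )
    profile.cnv_score = score
    profile.cnv_correlation = corr
    profile.call = call
    out = pd.DataFrame(
        {"cnv_score": score, "cnv_correlation": corr, "call": call},
        index=pd.Index(profile.barcodes, name="barcode"),
    )
    if clusters is not None:
        clusters = np.asarray(clusters)
        cluster_call = np.empty(n, dtype=object)
        for c in np.unique(clusters):
            rows = clusters == c
            vals, counts = np.unique(call[rows], return_counts=True)
            best = vals[np.lexsort((vals, -counts))[0]]
            if counts.max() / rows.sum() < 1.0 - cluster_disagreement:
                best = "unassigned"
            cluster_call[rows] = best
        out["cluster_call"] = cluster_call
    return out
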