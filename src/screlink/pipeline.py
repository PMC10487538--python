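"""End-to-end orchestration of the matched-multiome analysis.

``run_pipeline`` drives the full chain on an in-memory cohort: per-sample QC
and doublet removal in both modalities, RNA reduction/clustering/cell-typing,
per-patient CNV inference and malignancy calls, ATAC iterative LSI, label
transfer with imputed expression, pseudobulk peak calling + iterative overlap
merge, metacell peak-to-gene linkage, k-means link clustering, cancer-specific
enhancer calling, regulatory load, male-vs-female differential expression
with gene-set enrichment, and motif scanning/enrichment on enhancer
sequences. Every stage is seeded; a fixed seed gives byte-identical output
tables.

Desk-scale defaults: the synthetic genome has ~2,000 genes, so the RNA QC
gene floor is scaled down from the patient-scale default (no cell can express
2,000 of 2,000 genes); all other thresholds keep their patient-scale values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import cnv as cnv_mod
from . import differential, enhancer_analysis, linkage, motif, qc, reduce_cluster
from .io_intervals import CountsMatrix, write_bed
from .synthetic_data import Cohort, motif_fixture

__all__ = ["PipelineConfig", "run_pipeline", "link_recovery", "permuted_null_links"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # RNA QC (desk-scale gene floor; see module docstring)
    rna_umi_min: int = 2000
    rna_genes_min: int = 800
    rna_mito_max: float = 25.0
    # ATAC QC
    tss_threshold_log10: float = 0.9
    gmm_fallback_floor: float = 3.0
    # doublets
    doublet_rate_per_1000: float = 8.0
    doublet_filter_ratio: float = 1.0
    doublet_k: int = 25
    # reduction / clustering
    n_hvg: int = 2000
    n_pcs: int = 50
    use_dims: int = 30
    resolution: float = 0.8
    knn: int = 20
    lsi_n_var: int = 25_000
    lsi_cor_cutoff: float = 0.75
    # transfer
    transfer_k: int = 15
    impute_k: int = 1
    impute_depth_quantile: float = 0.2
    min_prediction_score: float = 0.5
    # cluster filters
    rna_mean_min: float = 5000.0
    atac_mean_min: float = 5000.0
    # CNV
    cnv_expr_cutoff: float = 0.1
    cnv_window: int = 101
    cnv_denoise_sd: float = 1.5
    # peak calling + linkage
    peak_mean_count_min: float = 0.16
    metacell_k: int = 100
    n_metacells: int | None = None       # default: n_cells/20, capped at 500
    metacell_max_shared: int = 80
    link_max_dist: int = 250_000
    link_r_min: float = 0.45
    link_fdr_max: float = 1e-12
    kmeans_k: int = 5
    # DE (patient-scale values)
    de_logfc_threshold: float = 0.25
    de_min_pct: float = 0.5
    de_min_diff_pct: float = 0.25
    de_max_cells: int = 500
    de_padj_max: float = 0.01
    # selection of upregulated linked genes
    up_log2fc_min: float = 1.0
    up_padj_max: float = 0.01
    # enrichment
    enrich_q_max: float = 0.01
    # motifs
    motif_q_max: float = 0.01
    motif_fdr_max: float = 0.01
    motif_log2fc_min: float = 1.0


# ---------------------------------------------------------------------------
# Modality QC
# ---------------------------------------------------------------------------

def _rna_doublet_reducer(X):
    from sklearn.decomposition import TruncatedSVD

    ln = reduce_cluster.log_normalize(X)
    return TruncatedSVD(n_components=20, random_state=0).fit_transform(ln)


def _atac_doublet_reducer(X):
    from sklearn.decomposition import TruncatedSVD

    mat = reduce_cluster.tfidf(X)
    return TruncatedSVD(n_components=20, random_state=0).fit_transform(mat)


def qc_rna(rna: CountsMatrix, cfg: PipelineConfig):
    """Per-sample outlier filtering + doublet removal for RNA."""
    kept_parts, tables = [], []
    for s in sorted(rna.obs["sample"].unique()):
        sub = rna.subset_cells((rna.obs["sample"] == s).to_numpy())
        kept, table = qc.rna_qc_filter(
            sub, umi_min=cfg.rna_umi_min, genes_min=cfg.rna_genes_min,
            mito_max=cfg.rna_mito_max,
        )
        scores = qc.doublet_scores(
            kept, _rna_doublet_reducer, k=cfg.doublet_k, seed=cfg.seed
        )
        kept, _ = qc.remove_top_doublets(
            kept, scores, cfg.doublet_rate_per_1000, cfg.doublet_filter_ratio
        )
        table["kept_final"] = table.index.isin(kept.barcodes)
        tables.append(table)
        kept_parts.append(kept)
    merged = _concat_cells(kept_parts)
    return merged, pd.concat(tables)


def qc_atac(atac: CountsMatrix, gene_models, cfg: PipelineConfig):
    """Per-sample GMM depth + TSS filtering + doublet removal for ATAC."""
    kept_parts, tables = [], []
    for s in sorted(atac.obs["sample"].unique()):
        sub = atac.subset_cells((atac.obs["sample"] == s).to_numpy())
        frags = sub.cell_totals()
        cut = qc.gmm_depth_threshold(
            np.log10(np.maximum(frags, 1)), seed=cfg.seed,
            fallback_floor=cfg.gmm_fallback_floor,
        )
        depth_ok = np.log10(np.maximum(frags, 1)) >= cut
        scores = qc.tss_scores(sub, gene_models)
        tss_ok = np.log10(scores + 1.0) >= cfg.tss_threshold_log10
        keep = depth_ok & tss_ok
        table = pd.DataFrame(
            {
                "n_fragments": frags.astype(int),
                "tss_score": scores,
                "depth_cutoff_log10": cut,
                "pass_depth": depth_ok,
                "pass_tss": tss_ok,
            },
            index=pd.Index(sub.barcodes, name="barcode"),
        )
        kept = sub.subset_cells(keep)
        dscores = qc.doublet_scores(
            kept, _atac_doublet_reducer, k=cfg.doublet_k, seed=cfg.seed
        )
        kept, _ = qc.remove_top_doublets(
            kept, dscores, cfg.doublet_rate_per_1000, cfg.doublet_filter_ratio
        )
        tables.append(table)
        kept_parts.append(kept)
    merged = _concat_cells(kept_parts)
    return merged, pd.concat(tables)


def _concat_cells(parts: list[CountsMatrix]) -> CountsMatrix:
    X = sp.vstack([p.X for p in parts], format="csr")
    barcodes = [b for p in parts for b in p.barcodes]
    obs = pd.concat([p.obs for p in parts])
    return CountsMatrix(X, barcodes, list(parts[0].features),
                        parts[0].feature_kind, obs)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def rna_stage(rna_kept: CountsMatrix, marker_genes: dict, cfg: PipelineConfig):
    """Reduction, clustering and cluster-majority cell typing for RNA."""
    ln = reduce_cluster.log_normalize(rna_kept)
    mito_cols = np.array([f.startswith("MT-") for f in rna_kept.features])
    pct_mito = (
        100.0 * np.asarray(rna_kept.X[:, mito_cols].sum(axis=1)).ravel()
        / np.maximum(rna_kept.cell_totals(), 1)
    )
    hvg = reduce_cluster.select_hvg(rna_kept, n_top=min(cfg.n_hvg, rna_kept.n_features))
    scaled = reduce_cluster.scale_and_regress(ln[:, hvg].toarray(), covariate=pct_mito)
    space = reduce_cluster.pca(
        scaled, n_components=min(cfg.n_pcs, scaled.shape[1]),
        depth=rna_kept.cell_totals(), barcodes=rna_kept.barcodes,
    )
    space = reduce_cluster.batch_center(space, rna_kept.obs["sample"].to_numpy())
    space.retained_dims = np.arange(min(cfg.use_dims, space.embedding.shape[1]))
    clusters = reduce_cluster.cluster_graph(
        space, k_nn=cfg.knn, resolution=cfg.resolution, seed=cfg.seed
    )
    mscores = reduce_cluster.marker_scores(ln, rna_kept.features, marker_genes)
    cell_label = mscores.idxmax(axis=1).to_numpy()
    clusters = reduce_cluster.assign_cluster_celltypes(clusters, cell_label)
    cell_type = np.array([clusters.cluster_celltype[c] for c in clusters.labels])
    return {
        "lognorm": ln, "hvg": hvg, "space": space, "clusters": clusters,
        "cell_type": cell_type, "pct_mito": pct_mito,
    }


def cnv_stage(rna_kept, ln, cell_type, gene_models, cfg: PipelineConfig):
    """Per-patient CNV residuals + malignancy calls for male samples."""
    calls = []
    samples = rna_kept.obs["sample"].to_numpy()
    for s in ("P1", "P2"):
        rows = np.flatnonzero(samples == s)
        if rows.size == 0:
            continue
        ref = np.isin(cell_type[rows], ["macrophage", "endothelial"])
        profile = cnv_mod.infer_cnv(
            ln[rows], list(rna_kept.features), gene_models, ref,
            [rna_kept.barcodes[i] for i in rows],
            expr_cutoff=cfg.cnv_expr_cutoff, window=cfg.cnv_window,
            denoise_sd=cfg.cnv_denoise_sd,
        )
        df = cnv_mod.classify_malignant(profile)
        df["sample"] = s
        calls.append(df)
    return pd.concat(calls) if calls else pd.DataFrame()


def atac_stage(atac_kept: CountsMatrix, gene_models, rna_ref, cfg: PipelineConfig):
    """LSI, clustering, label transfer and cluster filtering for ATAC."""
    space = reduce_cluster.iterative_lsi(
        atac_kept, n_var=cfg.lsi_n_var, dims=cfg.use_dims,
        cor_cutoff=cfg.lsi_cor_cutoff, seed=cfg.seed,
    )
    space = reduce_cluster.batch_center(space, atac_kept.obs["sample"].to_numpy())
    clusters = reduce_cluster.cluster_graph(
        space, k_nn=cfg.knn, resolution=cfg.resolution, seed=cfg.seed
    )
    activity = reduce_cluster.gene_activity(atac_kept, gene_models)
    transfer, imputed = reduce_cluster.label_transfer(
        rna_ref, activity, k=cfg.transfer_k, impute_k=cfg.impute_k,
        min_score=cfg.min_prediction_score, constrain_by_sample=True,
    )
    clusters = reduce_cluster.assign_cluster_celltypes(
        clusters, transfer["label"].to_numpy()
    )
    retained = ~transfer["excluded"].to_numpy()
    _, cluster_mask = reduce_cluster.filter_clusters(
        clusters, atac_kept.cell_totals(), mean_min=cfg.atac_mean_min
    )
    keep = retained & cluster_mask
    return {
        "space": space, "clusters": clusters, "transfer": transfer,
        "imputed": imputed, "keep": keep,
    }


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def link_recovery(filtered_links: pd.DataFrame, truth_links: pd.DataFrame) -> dict:
    """Recall/precision of detected (peak, gene) pairs against the planted
    truth table."""
    detected = set(zip(filtered_links["peak_id"], filtered_links["gene_id"]))
    planted = set(zip(truth_links["peak_id"], truth_links["gene_id"]))
    tp = len(detected & planted)
    return {
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(detected) if detected else float("nan"),
        "n_detected": len(detected),
        "n_planted": len(planted),
        "n_true_positive": tp,
    }


def permuted_null_links(
    agg_peaks: np.ndarray,
    agg_rna: np.ndarray,
    peaks,
    gene_models,
    peak_classes,
    cfg: PipelineConfig,
    n_perm: int = 20,
    seed: int = 0,
) -> list[int]:
    """Number of passing links after permuting metacell labels on the RNA
    side, per permutation."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(agg_rna.shape[0])
        links = linkage.correlate_peak_gene(
            agg_peaks, agg_rna[perm], peaks, gene_models,
            peak_classes=peak_classes, max_dist=cfg.link_max_dist,
        )
        kept = linkage.filter_links(
            links, r_min=cfg.link_r_min, fdr_max=cfg.link_fdr_max
        )
        out.append(int(len(kept)))
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cohort: Cohort, cfg: PipelineConfig | None = None,
                 outdir: str | None = None) -> dict:
    """Run the full analysis on a cohort; returns a dict of intermediates
    and result tables. With ``outdir``, writes the output TSV/BED files."""
    cfg = cfg or PipelineConfig()
    truth = cohort.truth
    gene_models = cohort.genes

    # --- RNA ---------------------------------------------------------------
    rna_kept, rna_qc_table = qc_rna(cohort.rna, cfg)
    rna = rna_stage(rna_kept, truth.marker_genes, cfg)
    cnv_calls = cnv_stage(rna_kept, rna["lognorm"], rna["cell_type"],
                          gene_models, cfg)

    # RNA cluster filter (mean depth + label)
    _, rna_cluster_mask = reduce_cluster.filter_clusters(
        rna["clusters"], rna_kept.cell_totals(), mean_min=cfg.rna_mean_min
    )

    samples = rna_kept.obs["sample"].to_numpy()
    is_male = np.isin(samples, ["P1", "P2"])
    epi = rna["cell_type"] == "epi_tumor"
    tumor_call = pd.Series("none", index=rna_kept.barcodes)
    if len(cnv_calls):
        tumor_call.loc[cnv_calls.index] = cnv_calls["call"]
    male_tumor = np.flatnonzero(
        is_male & epi & (tumor_call.to_numpy() == "tumor") & rna_cluster_mask
    )
    if male_tumor.size < 3:       # fall back to the epithelial label alone
        male_tumor = np.flatnonzero(is_male & epi & rna_cluster_mask)
    female_tumor = np.flatnonzero(~is_male & epi & rna_cluster_mask)

    # --- male vs female DE + enrichment ------------------------------------
    de = differential.wilcoxon_de(
        rna["lognorm"], male_tumor, female_tumor, list(rna_kept.features),
        logfc_threshold=cfg.de_logfc_threshold, min_pct=cfg.de_min_pct,
        min_diff_pct=cfg.de_min_diff_pct, max_cells_per_ident=cfg.de_max_cells,
        padj_max=cfg.de_padj_max, seed=cfg.seed,
    )
    gene_sets = _fixture_gene_sets(cohort)
    up_genes = de.loc[de["log2fc"] > cfg.de_logfc_threshold, "gene_id"].tolist()
    enrichment = differential.hypergeom_enrich(
        up_genes, gene_sets, list(rna_kept.features), q_max=cfg.enrich_q_max
    ) if up_genes else pd.DataFrame()

    # --- ATAC ---------------------------------------------------------------
    male_rna_mask = is_male & rna_cluster_mask
    male_rna = rna_kept.subset_cells(male_rna_mask)
    # Imputation uses depth-downsampled reference profiles: neighbor
    # selection favors some reference cells over others, and without equal
    # depths the depth-dependence of log-normalized values (dropout) would
    # turn that usage bias into a systematic per-cell-type expression bias.
    target_depth = int(np.quantile(male_rna.cell_totals(), cfg.impute_depth_quantile))
    thinned = reduce_cluster.downsample_counts(male_rna, target_depth, seed=cfg.seed)
    ref = reduce_cluster.RnaReference(
        lognorm=reduce_cluster.log_normalize(thinned),
        genes=list(rna_kept.features),
        hvg_idx=rna["hvg"],
        components=rna["space"].components,
        embedding=rna["space"].embedding[np.flatnonzero(male_rna_mask)],
        labels=rna["cell_type"][male_rna_mask],
        samples=samples[male_rna_mask],
        barcodes=list(male_rna.barcodes),
    )
    atac_kept, atac_qc_table = qc_atac(cohort.atac, gene_models, cfg)
    atac = atac_stage(atac_kept, gene_models, ref, cfg)
    final_mask = atac["keep"]
    atac_final = atac_kept.subset_cells(final_mask)
    final_idx = np.flatnonzero(final_mask)
    labels_final = atac["transfer"]["label"].to_numpy()[final_idx]
    imputed_final = atac["imputed"][final_idx]
    space_final = atac["space"].subset(final_mask)

    # --- peaks --------------------------------------------------------------
    cluster_calls = linkage.call_cluster_peaks(
        atac_final, labels_final, mean_count_min=cfg.peak_mean_count_min
    )
    universal = linkage.iterative_overlap_merge(
        list(cluster_calls.values()), fixed_width=cohort.config.tile_width
    )
    peak_classes = linkage.annotate_peaks(universal, gene_models)
    peak_counts = linkage.peak_matrix_from_tiles(atac_final, universal)

    # --- metacells + linkage -----------------------------------------------
    n_cells = atac_final.n_cells
    n_groups = cfg.n_metacells or min(500, int(np.ceil(n_cells / 20)))
    grouping = linkage.make_metacells(
        space_final, k=cfg.metacell_k, n_groups=n_groups,
        max_shared=cfg.metacell_max_shared, seed=cfg.seed,
    )
    agg_peaks = linkage.aggregate_metacells(peak_counts, grouping, lognorm=True)
    agg_rna = linkage.aggregate_metacell_means(imputed_final, grouping)
    all_links = linkage.correlate_peak_gene(
        agg_peaks, agg_rna, universal, gene_models,
        peak_classes=peak_classes, max_dist=cfg.link_max_dist,
    )
    links = linkage.filter_links(
        all_links, r_min=cfg.link_r_min, fdr_max=cfg.link_fdr_max
    )

    # per-type profiles for link clustering
    peak_ln = reduce_cluster.log_normalize(peak_counts)
    ptypes = sorted(set(labels_final))
    peak_prof = pd.DataFrame(
        {
            t: np.asarray(peak_ln[labels_final == t].mean(axis=0)).ravel()
            for t in ptypes
        },
        index=universal.ids,
    )
    gene_prof = pd.DataFrame(
        {
            t: np.asarray(imputed_final[labels_final == t].mean(axis=0)).ravel()
            for t in ptypes
        },
        index=list(rna_kept.features),
    )
    links = linkage.kmeans_links(
        links, peak_prof, gene_prof, k=cfg.kmeans_k, seed=cfg.seed
    )

    # --- enhancer analysis ---------------------------------------------------
    call_set = enhancer_analysis.call_cancer_specific(
        links, universal, truth.reference_enhancers
    )
    load = enhancer_analysis.regulatory_load(call_set, links)
    up_linked = enhancer_analysis.select_upregulated_linked_genes(
        de, call_set, links,
        log2fc_min=cfg.up_log2fc_min, padj_max=cfg.up_padj_max,
    )
    peak_id_list = list(universal.ids)
    superenh = enhancer_analysis.superenhancer_candidates(
        links, universal, peak_metacells=agg_peaks, peak_ids=peak_id_list
    )

    # --- motifs ---------------------------------------------------------------
    seqs, meme_text, _ = motif_fixture(cohort)
    pwms = _read_meme_text(meme_text)
    target = {p: seqs[p] for p in call_set.cancer_specific if p in seqs}
    background = {
        p: s for p, s in seqs.items() if p not in set(call_set.cancer_specific)
    }
    if target and background:
        enrich_motifs = motif.motif_enrichment(
            target, background, pwms,
            fdr_max=cfg.motif_fdr_max, log2fc_min=cfg.motif_log2fc_min,
        )
        hits = motif.scan_all(pwms, target)
        tf_expr = _malignant_tf_expression(rna["lognorm"], rna_kept, male_tumor)
        ranked = motif.rank_hits_by_tf_expression(hits, tf_expr, q_max=cfg.motif_q_max)
    else:
        enrich_motifs, hits, ranked = pd.DataFrame(), pd.DataFrame(), pd.DataFrame()

    result = {
        "config": cfg,
        "rna_kept": rna_kept, "rna_qc": rna_qc_table, "rna": rna,
        "cnv_calls": cnv_calls, "de": de, "enrichment": enrichment,
        "atac_kept": atac_kept, "atac_qc": atac_qc_table,
        "atac": atac, "atac_final": atac_final, "labels_final": labels_final,
        "space_final": space_final, "grouping": grouping,
        "universal_peaks": universal, "peak_classes": peak_classes,
        "agg_peaks": agg_peaks, "agg_rna": agg_rna,
        "all_links": all_links, "links": links,
        "call_set": call_set, "regulatory_load": load,
        "up_linked_genes": up_linked, "superenhancers": superenh,
        "motif_enrichment": enrich_motifs, "motif_hits": hits,
        "motif_ranked": ranked,
    }
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _fixture_gene_sets(cohort: Cohort) -> dict:
    t = cohort.truth
    up = t.de_genes.loc[t.de_genes["direction"] == "up", "gene_id"].tolist()
    return {
        "SET_MALE_UP": up,
        "SET_EPI_MARKERS": list(t.marker_genes["epi_tumor"]),
        "SET_DECOY": [g.gene_id for g in cohort.genes[:50]],
    }


def _read_meme_text(text: str):
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".meme", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return motif.read_meme(path)
    finally:
        os.unlink(path)


def _malignant_tf_expression(ln, rna_kept, malignant_rows) -> dict:
    sub = ln[malignant_rows]
    sums = np.asarray(sub.sum(axis=0)).ravel()
    return dict(zip(rna_kept.features, sums))


def _write_outputs(result: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)

    def w(df: pd.DataFrame, name: str, index=False):
        df.to_csv(os.path.join(outdir, name), sep="\t", index=index,
                  float_format="%.6g")

    links = result["links"]
    cols = ["peak_id", "gene_id", "r", "p", "fdr", "distance_bp", "peak_class",
            "kmeans_cluster"]
    w(links[[c for c in cols if c in links.columns]], "links.tsv")
    w(result["de"], "de.tsv")
    if len(result["cnv_calls"]):
        w(result["cnv_calls"].reset_index(), "cnv_calls.tsv")
    if len(result["enrichment"]):
        w(result["enrichment"], "enrichment.tsv")
    cs = result["call_set"]
    write_bed(
        result["universal_peaks"].subset(cs.cancer_specific),
        os.path.join(outdir, "cancer_specific.bed"),
    )
    load = result["regulatory_load"]
    pd.DataFrame(
        [
            ("cancer_specific", load["cancer_mean"], load["cancer_total_genes"]),
            ("non_epithelial", load["other_mean"], load["other_total_genes"]),
        ],
        columns=["peak_set", "mean_linked_genes", "total_linked_genes"],
    ).assign(wilcoxon_p=load["p"]).pipe(w, "regulatory_load.tsv")
    w(result["up_linked_genes"], "linked_upregulated_genes.tsv")
    w(result["superenhancers"], "superenhancer_candidates.tsv")
    if len(result["motif_enrichment"]):
        w(result["motif_enrichment"], "motif_enrichment.tsv")
    if len(result["motif_ranked"]):
        w(result["motif_ranked"], "motif_ranked.tsv")
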