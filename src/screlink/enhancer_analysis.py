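"""Cancer-specific enhancer calling and downstream regulatory statistics.

Distal peaks from tumor-enriched link clusters are partitioned against a
reference normal-epithelium enhancer set by 1-bp-overlap subtraction: a peak
sharing even a single base with a reference enhancer is reference-overlapping;
the remainder are cancer-specific. The regulatory load (linked genes per
peak) of the cancer-specific set is compared to non-epithelial distal peaks
with a two-sided rank-sum test. Genes both upregulated in the DE contrast
and linked to a cancer-specific enhancer form the candidate driver list, and
genes with many mutually correlated, genomically clustered promoter links
are flagged as super-enhancer candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import rank_sum_test
from .io_intervals import PeakSet, find_overlaps

__all__ = [
    "EnhancerCallSet",
    "call_cancer_specific",
    "regulatory_load",
    "select_upregulated_linked_genes",
    "superenhancer_candidates",
]


@dataclass
class EnhancerCallSet:
    """Partition of tumor-enriched peaks against a reference enhancer set."""

    cancer_enriched: list[str]          # peak ids from tumor-enriched clusters
    reference_overlapping: list[str]
    cancer_specific: list[str]
    linked_gene_count: pd.Series        # per cancer-enriched peak

    def __post_init__(self):
        spec, ref = set(self.cancer_specific), set(self.reference_overlapping)
        if spec & ref:
            raise ValueError("cancer_specific and reference_overlapping intersect")
        if spec | ref != set(self.cancer_enriched):
            raise ValueError("partition does not cover cancer_enriched")


def call_cancer_specific(
    links: pd.DataFrame,
    peaks: PeakSet,
    reference_enhancers: PeakSet,
    tumor_celltype: str = "epi_tumor",
    min_overlap: int = 1,
) -> EnhancerCallSet:
    """Partition tumor-enriched link peaks by reference overlap.

    ``links`` must carry ``cluster_celltype`` (from the k-means stage);
    peaks of links whose cluster is labeled ``tumor_celltype`` are the
    cancer-enriched set. Any overlap of at least ``min_overlap`` bp with the
    reference BED (half-open semantics: adjacency is no overlap) moves a
    peak to ``reference_overlapping``; the rest are ``cancer_specific``.
    """
    if "cluster_celltype" not in links.columns:
        raise ValueError("links need a cluster_celltype column (run kmeans_links)")
    tumor_links = links[links["cluster_celltype"] == tumor_celltype]
    enriched_ids = sorted(tumor_links["peak_id"].unique())
    if len(reference_enhancers) == 0:
        warnings.warn(
            "reference enhancer set is EMPTY: every tumor-enriched peak will "
            "be called cancer-specific",
            stacklevel=2,
        )
    enriched_peaks = peaks.subset(enriched_ids)
    pairs = find_overlaps(enriched_peaks, reference_enhancers, min_overlap=min_overlap)
    overlapping = sorted({pid for pid, _, _ in pairs})
    specific = sorted(set(enriched_ids) - set(overlapping))
    counts = tumor_links.groupby("peak_id")["gene_id"].nunique()
    return EnhancerCallSet(
        cancer_enriched=enriched_ids,
        reference_overlapping=overlapping,
        cancer_specific=specific,
        linked_gene_count=counts.reindex(enriched_ids).fillna(0).astype(int),
    )


def regulatory_load(
    call_set: EnhancerCallSet,
    links: pd.DataFrame,
    comparison_celltypes: list[str] | None = None,
    tumor_celltype: str = "epi_tumor",
) -> dict:
    """Mean linked genes per peak: cancer-specific vs non-epithelial distal
    peaks, with a two-sided rank-sum p and total distinct linked genes.

    Counts come from the filtered distal link table. Returns a dict with
    ``cancer_mean``, ``other_mean``, ``p``, ``cancer_total_genes``,
    ``other_total_genes`` and the two per-peak count series.
    """
    per_peak = links.groupby("peak_id")["gene_id"].nunique()
    cancer_ids = [p for p in call_set.cancer_specific if p in per_peak.index]
    if comparison_celltypes is None:
        other_links = links[links["cluster_celltype"] != tumor_celltype]
    else:
        other_links = links[links["cluster_celltype"].isin(comparison_celltypes)]
    other_ids = sorted(set(other_links["peak_id"].unique()) - set(cancer_ids))
    cancer_counts = per_peak.loc[cancer_ids]
    other_counts = per_peak.loc[other_ids]
    if len(cancer_counts) and len(other_counts):
        if cancer_counts.nunique() == 1 and other_counts.nunique() == 1 and \
                cancer_counts.iloc[0] == other_counts.iloc[0]:
            p = 1.0
        else:
            _, p = rank_sum_test(
                cancer_counts.to_numpy(float), other_counts.to_numpy(float),
                method="asymptotic",
            )
    else:
        p = float("nan")
    return {
        "cancer_mean": float(cancer_counts.mean()) if len(cancer_counts) else float("nan"),
        "other_mean": float(other_counts.mean()) if len(other_counts) else float("nan"),
        "p": float(p),
        "cancer_total_genes": int(
            links[links["peak_id"].isin(cancer_ids)]["gene_id"].nunique()
        ),
        "other_total_genes": int(
            links[links["peak_id"].isin(other_ids)]["gene_id"].nunique()
        ),
        "cancer_counts": cancer_counts,
        "other_counts": other_counts,
    }


def select_upregulated_linked_genes(
    de_results: pd.DataFrame,
    call_set: EnhancerCallSet,
    links: pd.DataFrame,
    log2fc_min: float = 1.0,
    padj_max: float = 0.01,
) -> pd.DataFrame:
    """Genes passing the upregulation cutoffs (``log2fc > log2fc_min`` and
    ``padj < padj_max``) that are linked to at least one cancer-specific
    peak. Returns gene rows with their enhancer peak ids."""
    up = de_results[
        (de_results["log2fc"] > log2fc_min) & (de_results["padj"] < padj_max)
    ]
    spec = set(call_set.cancer_specific)
    linked = links[links["peak_id"].isin(spec)]
    gene_to_peaks = linked.groupby("gene_id")["peak_id"].agg(
        lambda s: ",".join(sorted(set(s)))
    )
    out = up[up["gene_id"].isin(gene_to_peaks.index)].copy()
    out["enhancer_peaks"] = out["gene_id"].map(gene_to_peaks)
    return out.sort_values(["padj", "gene_id"], kind="stable").reset_index(drop=True)


def superenhancer_candidates(
    links: pd.DataFrame,
    peaks: PeakSet,
    peak_metacells: np.ndarray | None = None,
    peak_ids: list[str] | None = None,
    min_links_per_gene: int = 5,
    span_window: int = 150_000,
    pairwise_r_min: float = 0.45,
) -> pd.DataFrame:
    """Genes whose promoters are linked by many clustered, co-correlated
    distal peaks.

    A gene is flagged iff more than ``min_links_per_gene`` distal peaks link
    to it, the constituent peaks all lie within ``span_window`` of each
    other, and (when metacell accessibility is provided) the median pairwise
    Pearson correlation among constituents is >= ``pairwise_r_min``. Emits
    one row per flagged gene with its constituents and merged span.
    """
    by_id = peaks.by_id()
    pos = {p: i for i, p in enumerate(peak_ids)} if peak_ids is not None else {}
    rows = []
    for gene, sub in links.groupby("gene_id"):
        pids = sorted(sub["peak_id"].unique())
        if len(pids) <= min_links_per_gene:
            continue
        ivs = [by_id[p] for p in pids if p in by_id]
        if len(ivs) != len(pids):
            continue
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            continue
        lo = min(iv.start for iv in ivs)
        hi = max(iv.end for iv in ivs)
        if hi - lo > span_window:
            continue
        med_r = np.nan
        if peak_metacells is not None and peak_ids is not None:
            cols = [pos[p] for p in pids if p in pos]
            if len(cols) >= 2:
                sub_m = np.asarray(peak_metacells)[:, cols]
                cm = np.corrcoef(sub_m.T)
                upper = cm[np.triu_indices_from(cm, k=1)]
                med_r = float(np.median(upper))
                if med_r < pairwise_r_min:
                    continue
        rows.append(
            (
                gene, len(pids), ",".join(pids),
                next(iter(chroms)), int(lo), int(hi), med_r,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_constituents", "constituent_peaks",
            "chrom", "span_start", "span_end", "median_pairwise_r",
        ],
    )
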