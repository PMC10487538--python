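"""Synthetic matched scRNA/scATAC cohort with planted ground truth.

The generator emulates the structure of a two-patient male-breast-cancer
multiome plus a female comparator cohort: four cell types (malignant
epithelium, macrophages, fibroblasts, endothelium), patient-specific tumor
transcriptomes over shared stromal profiles, planted copy-number segments,
planted distal-enhancer-to-gene links with a tunable metacell-level Pearson
correlation, planted doublets and low-quality cells, and a male-vs-female
differential-expression contrast with hard-zero sex-specific genes.

Why links are planted at the *population* level
-----------------------------------------------
The pipeline correlates peak accessibility against expression *imputed* from
a different set of cells (the RNA reference), so any coupling injected as a
per-cell latent would be averaged away by the method under test. Real
peak-to-gene signal is covariation across cell subpopulations. Each planted
link therefore couples a peak and a gene through their cell-type profiles:
the peak's per-(type, patient) accessibility profile is

    x = rho * y_hat + sqrt(1 - rho^2) * c_hat

where ``y_hat`` is the standardized indicator of the target gene's host cell
type, ``c_hat`` is a standardized within-epithelium patient contrast
orthogonalized against ``y_hat`` (a profile no gene follows, so it cannot
create unplanted links), and ``rho`` is the configured target metacell
correlation. The gene's expression follows ``y_hat``. At the rate level the
metacell Pearson correlation between the pair is then ``rho`` up to counting
noise.

The synthetic genome is desk-scale: three chromosomes plus a mitochondrial
contig, ~3,200 genes, 32,000 x 500-bp tiles, entirely defined by the emitted
gene TSV. Chromosome 1 carries the planted linkage loci (25-kb blocks of
five genes followed by a gene-free zone holding at most one planted
enhancer); chromosome 2 carries cell-type marker genes, CNV segments,
patient-specific tumor genes, sex-specific genes and DE genes in its first
2 Mb, and a gene desert with cell-type marker tiles in its second 2 Mb (far
enough from every gene that desert peaks generate no candidate pairs);
chromosome 3 carries the decoy peaks among housekeeping genes only — decoys
are kept out of cis range of planted targets because a peak in cis of a
cell-type-specific gene genuinely covaries with it, which would make
truth-based precision ill-defined.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_intervals import (
    CountsMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_counts_mtx,
    write_gene_models,
)

__all__ = ["GeneratorConfig", "SyntheticTruth", "Cohort", "generate_cohort", "emit_fixture"]

CELL_TYPES = ["epi_tumor", "macrophage", "fibroblast", "endothelial"]
MALE_SAMPLES = ["P1", "P2"]
ALL_SAMPLES = ["P1", "P2", "F"]

# ATAC groups: (cell type, patient), patients male only.
ATAC_GROUPS = [(t, s) for t in CELL_TYPES for s in MALE_SAMPLES]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort. ``rng_seed`` is mandatory.

    Defaults define the study-scale fixture: 2,000 RNA cells per sample
    (P1, P2 and the female comparator F — the RNA reference is deliberately
    larger than the ATAC cohort, as in the underlying study designs), 1,500
    ATAC cells per male patient (~3,000 total), a ~3,200-gene genome on
    32,000 tiles, 70 planted enhancer peaks carrying 100 peak-to-gene links
    at metacell effect 0.7, and >= 5,000 decoy peaks.
    """

    rng_seed: int = 0
    # cohort sizes
    n_rna_cells_per_sample: int = 2000
    n_atac_cells_per_sample: int = 1500
    # genome layout
    tile_width: int = 500
    chr1_blocks: int = 240
    chr3_blocks: int = 240
    block_bp: int = 25_000
    genes_per_block: int = 5
    chr2_genes: int = 800
    chr2_gene_spacing: int = 2_500
    chr2_len: int = 4_000_000
    n_mito_genes: int = 20
    # planted links
    n_link_peaks: int = 70
    n_two_target_lineage: int = 12
    link_effect_r: float = 0.7
    # planted CNV: (sample, fold, span in genes); positions fixed by layout
    cnv_segments: tuple = (("P1", 1.5, 250), ("P2", 1.5, 250))
    # planted DE (male tumor vs female tumor)
    n_de_up: int = 20
    n_de_down: int = 8
    n_linked_de: int = 20
    de_log2fc: float = 2.0
    n_sex_genes: int = 6
    # program sizes: many genes with moderate effects, as in real cell types
    n_marker_genes: int = 80
    n_patient_genes: int = 90
    # nuisance cells
    doublet_rate: float = 0.01
    rna_low_quality_frac: float = 0.05
    rna_high_mito_frac: float = 0.03
    atac_low_quality_frac: float = 0.05
    # depth and noise
    rna_depth_meanlog: float = float(np.log(12_000))
    rna_depth_sdlog: float = 0.25
    atac_depth_meanlog: float = float(np.log(6_000))
    atac_depth_sdlog: float = 0.20
    low_quality_depth_factor: float = 0.08
    mito_beta: tuple = (2.0, 38.0)
    high_mito_beta: tuple = (12.0, 18.0)
    # NB size parameter: var = mu + mu^2/r; r=5 gives var/mean ~ 2 at
    # typical per-gene depth, matching droplet UMI data
    nb_dispersion: float = 5.0
    # per-sample depth shift (the only batch effect)
    sample_depth_factor: dict = field(
        default_factory=lambda: {"P1": 1.0, "P2": 1.15, "F": 0.9}
    )
    # cell-type composition
    type_props: dict = field(
        default_factory=lambda: {
            "epi_tumor": 0.40, "macrophage": 0.25,
            "fibroblast": 0.20, "endothelial": 0.15,
        }
    )
    # within-type activation gradient (program): marker intensity varies
    # per cell as ``program_lo + program_span * u`` with u ~ Uniform(0,1),
    # shared between modalities; mass-neutral via ballast compensation
    program_lo: float = 0.6
    program_span: float = 0.8
    # housekeeping cell-state slopes: every non-special gene responds to the
    # program with a random slope in [-hk_state_slope, +hk_state_slope],
    # giving genes genuine within-type variability (as real transcriptomes
    # have) so that finite-pool sampling offsets do not dominate their
    # metacell profiles
    hk_state_slope: float = 0.6
    # effect sizes (rate-multiplier contrasts); RNA boosts are moderate and
    # spread over many genes so that cell-type expression programs
    # (scattered across chr2) do not swamp the copy-number signal in
    # genome-ordered residuals
    marker_boost: float = 2.5
    atac_marker_boost: float = 6.0
    patient_gene_boost: float = 2.2
    link_gene_delta: float = 0.5
    link_peak_gamma: float = 0.5
    decoy_peak_boost: float = 3.0
    tss_boost: float = 10.0
    # reference ("normal mammary") enhancer set construction
    n_reference_overlap_cancer: int = 4
    n_reference_overlap_lineage: int = 20
    n_reference_random: int = 150

    def validate(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        for name in (
            "n_rna_cells_per_sample", "n_atac_cells_per_sample", "tile_width",
            "chr1_blocks", "block_bp", "genes_per_block", "chr2_genes",
            "chr2_len", "n_mito_genes", "n_link_peaks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.link_effect_r <= 1:
            raise ValueError("link_effect_r must be in [0, 1]")
        layout = build_layout(self)
        if self.n_link_peaks > len(layout.link_slots):
            raise ValueError(
                f"more planted link peaks ({self.n_link_peaks}) than available "
                f"link slots ({len(layout.link_slots)})"
            )
        n_peaks = len(layout.peak_tiles)
        n_links = sum(len(t) for t in layout.link_targets)
        if n_links > n_peaks:
            raise ValueError("more planted links than peaks")


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    genes: list            # list[GeneModel], chr1 then chr2 then chrM
    gene_index: dict       # gene_id -> global index
    n_tiles: int
    tile_chrom: np.ndarray
    tile_start: np.ndarray
    # tile-index sets
    tss_tiles: np.ndarray
    flank_tiles: np.ndarray
    peak_tiles: np.ndarray           # all nominal peak tiles (sorted)
    decoy_peak_tiles: np.ndarray
    promoter_peak_tiles: np.ndarray
    desert_marker_tiles: dict        # type -> tile idx array
    desert_uniform_tiles: np.ndarray
    atac_ballast_tiles: np.ndarray   # per-cell mass compensation (not peaks)
    patient_tiles: dict              # sample -> tile idx array
    marker_body_tiles: dict          # type -> tile idx array
    # link structure
    link_slots: list                 # candidate (block, tile_idx) pairs
    link_peak_tiles: np.ndarray
    link_hosts: list                 # host cell type per link peak
    link_targets: list               # list of gene-id lists per link peak
    # special gene-id groups
    marker_genes: dict               # type -> list of gene ids
    cnv_gene_ids: dict               # sample -> list of gene ids
    cnv_intervals: dict              # sample -> GenomicInterval
    patient_genes: dict              # sample -> list of gene ids
    male_only: list
    female_only: list
    de_up: list                      # chr2 DE-up genes (not linked)
    de_down: list
    linked_de: list                  # cancer-link target genes that are also DE-up
    ballast: list                    # per-class compositional balancer genes
    mito_genes: list


def _tile_of(chrom_offset: int, pos: int, tile_width: int) -> int:
    return chrom_offset + pos // tile_width


def build_layout(cfg: GeneratorConfig) -> GenomeLayout:
    """Deterministic genome layout derived purely from the config."""
    tw = cfg.tile_width
    chr1_len = cfg.chr1_blocks * cfg.block_bp
    chr3_len = cfg.chr3_blocks * cfg.block_bp
    if chr1_len % tw or cfg.chr2_len % tw or chr3_len % tw:
        raise ValueError("chromosome lengths must be tile-aligned")
    n1, n2, n3 = chr1_len // tw, cfg.chr2_len // tw, chr3_len // tw
    n_tiles = n1 + n2 + n3
    tile_chrom = np.array(["chr1"] * n1 + ["chr2"] * n2 + ["chr3"] * n3)
    tile_start = np.concatenate(
        [np.arange(n1) * tw, np.arange(n2) * tw, np.arange(n3) * tw]
    ).astype(np.int64)

    genes: list[GeneModel] = []
    gid = 0

    def add_gene(chrom, start, end, strand):
        nonlocal gid
        g = GeneModel(f"G{gid:04d}", GenomicInterval(chrom, start, end, id=f"G{gid:04d}"), strand)
        genes.append(g)
        gid += 1
        return g

    # chr1: blocks of genes_per_block 2-kb genes at 2-kb pitch, last one '-'
    for b in range(cfg.chr1_blocks):
        base = b * cfg.block_bp
        for j in range(cfg.genes_per_block):
            start = base + j * 2_000
            strand = "-" if j == cfg.genes_per_block - 1 else "+"
            add_gene("chr1", start, start + 2_000, strand)
    n_chr1_genes = gid

    # chr2: dense gene region in the first half
    for j in range(cfg.chr2_genes):
        start = j * cfg.chr2_gene_spacing
        add_gene("chr2", start, start + 2_000, "+")

    # chr3: decoy chromosome, same block layout as chr1 but housekeeping
    # genes only (keeping decoy peaks > 250 kb away from every planted
    # target gene keeps the planted truth unambiguous: a decoy in cis of a
    # cell-type-specific target would genuinely covary with it)
    for b in range(cfg.chr3_blocks):
        base = b * cfg.block_bp
        for j in range(cfg.genes_per_block):
            start = base + j * 2_000
            strand = "-" if j == cfg.genes_per_block - 1 else "+"
            add_gene("chr3", start, start + 2_000, strand)

    # chrM: mitochondrial genes (no tiles)
    mito_genes = []
    for j in range(cfg.n_mito_genes):
        g = GeneModel(
            f"MT-{j:02d}",
            GenomicInterval("chrM", j * 600, j * 600 + 500, id=f"MT-{j:02d}"),
            "+",
        )
        genes.append(g)
        mito_genes.append(g.gene_id)

    gene_index = {g.gene_id: i for i, g in enumerate(genes)}

    # TSS and flank tiles (nuclear genes)
    offsets = {"chr1": (0, chr1_len), "chr2": (n1, cfg.chr2_len),
               "chr3": (n1 + n2, chr3_len)}
    tss, flank = set(), set()
    for g in genes:
        if g.body.chrom == "chrM":
            continue
        off, clen = offsets[g.body.chrom]
        t0 = _tile_of(off, g.tss, tw)
        for d in (-1, 0, 1):
            t = t0 + d
            if off <= t < off + clen // tw:
                tss.add(t)
        for d in (-4, -3, -2, 2, 3, 4):
            t = t0 + d
            if off <= t < off + clen // tw:
                flank.add(t)
    flank -= tss
    tss_tiles = np.array(sorted(tss))
    flank_tiles = np.array(sorted(flank))

    # distal peak zones: tiles in [12.5 kb, 23 kb) of each block.
    # chr1 zones hold the planted link peaks (every third block, keeping
    # same-host-type loci >= 300 kb apart); chr3 zones hold the decoys.
    link_slots = []
    zone_lo, zone_hi = 12_500 // tw, 23_000 // tw
    for b in range(cfg.chr1_blocks):
        block_tile0 = b * cfg.block_bp // tw
        if b % 3 == 2:   # every third block offers a link slot (mid-zone tile)
            link_slots.append((b, block_tile0 + zone_lo + 8))
    chr3_zone_tiles = []
    chr3_tile0 = n1 + n2
    for b in range(cfg.chr3_blocks):
        block_tile0 = chr3_tile0 + b * cfg.block_bp // tw
        chr3_zone_tiles.extend(range(block_tile0 + zone_lo, block_tile0 + zone_hi))

    link_slots = link_slots[: cfg.n_link_peaks] if cfg.n_link_peaks <= len(link_slots) else link_slots
    link_peak_tiles = np.array([t for _, t in link_slots[: cfg.n_link_peaks]])
    link_blocks = [b for b, _ in link_slots[: cfg.n_link_peaks]]
    hosts = [CELL_TYPES[i % 4] for i in range(len(link_blocks))]

    # targets: genes 0 and 2 of the block (both '+', TSS 0 and 4 kb into block)
    lineage_idx = [i for i, h in enumerate(hosts) if h != "epi_tumor"]
    two_target_lineage = set(lineage_idx[:: max(1, len(lineage_idx) // max(cfg.n_two_target_lineage, 1))][: cfg.n_two_target_lineage])
    link_targets = []
    for i, b in enumerate(link_blocks):
        g0 = f"G{b * cfg.genes_per_block:04d}"
        g2 = f"G{b * cfg.genes_per_block + 2:04d}"
        if hosts[i] == "epi_tumor" or i in two_target_lineage:
            link_targets.append([g0, g2])
        else:
            link_targets.append([g0])

    decoy_tiles = np.array(sorted(chr3_zone_tiles))

    # chr2 gene-region promoter peaks: TSS tile of every 2nd chr2 gene
    promoter_peaks = []
    for j in range(0, cfg.chr2_genes, 2):
        promoter_peaks.append(_tile_of(n1, j * cfg.chr2_gene_spacing, tw))
    promoter_peak_tiles = np.array(sorted(set(promoter_peaks)))

    # chr2 desert: [2.25 Mb, 4 Mb)
    desert0 = n1 + 2_250_000 // tw
    desert_end = n1 + n2
    desert = np.arange(desert0, desert_end)
    desert_marker_tiles = {}
    p = 0
    for t in CELL_TYPES:
        desert_marker_tiles[t] = desert[p : p + 200]
        p += 200
    # patient-specific accessible tiles in tumor cells: strong enough that
    # the epithelial compartment reliably separates by patient, as matched
    # tumor scATAC data does
    patient_tiles = {"P1": desert[p : p + 200], "P2": desert[p + 200 : p + 400]}
    p += 400
    desert_uniform = desert[p : p + 400]
    p += 400
    atac_ballast = desert[p : p + 300]

    # Special genes are SCATTERED uniformly over chr2 positions (seeded by
    # the config): real genomes interleave cell-type programs with
    # housekeeping genes, and only that interleaving lets expression-based
    # CNV inference separate contiguous copy-number runs from expression
    # programs. CNV segments are *positional* runs — their fold applies to
    # whatever genes (special or not) sit inside them.
    def chr2_id(j):
        return f"G{n_chr1_genes + j:04d}"

    scatter_rng = np.random.default_rng((cfg.rng_seed * 2_654_435_761) % (2**31))
    order = scatter_rng.permutation(cfg.chr2_genes)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = sorted(order[cursor : cursor + k])
        cursor += k
        return [chr2_id(j) for j in out]

    marker_genes = {t: take(cfg.n_marker_genes) for t in CELL_TYPES}
    patient_genes = {"P1": take(cfg.n_patient_genes), "P2": take(cfg.n_patient_genes)}
    male_only = take(cfg.n_sex_genes)
    female_only = take(cfg.n_sex_genes)
    de_up = take(cfg.n_de_up)
    de_down = take(cfg.n_de_down)
    ballast = take(40)

    cnv_gene_ids, cnv_intervals = {}, {}
    starts = {"P1": 150, "P2": 450}
    for sample, fold, span in cfg.cnv_segments:
        lo = starts.get(sample, 180)
        ids = [chr2_id(j) for j in range(lo, lo + span)]
        cnv_gene_ids[sample] = ids
        first = genes[gene_index[ids[0]]].body
        last = genes[gene_index[ids[-1]]].body
        cnv_intervals[sample] = GenomicInterval("chr2", first.start, last.end, id=f"cnv_{sample}")

    # marker-gene body tiles (chr2, accessible in own type; NOT peaks)
    marker_body_tiles = {}
    for t, ids in marker_genes.items():
        tl = []
        for gidd in ids:
            g = genes[gene_index[gidd]]
            lo = _tile_of(n1, g.body.start, tw)
            hi = _tile_of(n1, g.body.end - 1, tw)
            tl.extend(range(lo, hi + 1))
        marker_body_tiles[t] = np.array(sorted(set(tl)))

    # linked DE genes: targets of epithelial link peaks, skipping the ones that
    # will be covered by the reference enhancer set (the first few epi peaks)
    epi_idx = [i for i, h in enumerate(hosts) if h == "epi_tumor"]
    skip = set(epi_idx[: cfg.n_reference_overlap_cancer])
    linked_de = []
    for i in epi_idx:
        if i in skip:
            continue
        for g in link_targets[i]:
            if len(linked_de) < cfg.n_linked_de:
                linked_de.append(g)

    peak_tiles = np.array(sorted(
        set(decoy_tiles) | set(link_peak_tiles) | set(promoter_peak_tiles)
        | set(np.concatenate(list(desert_marker_tiles.values())))
        | set(desert_uniform)
    ))

    return GenomeLayout(
        genes=genes, gene_index=gene_index, n_tiles=n_tiles,
        tile_chrom=tile_chrom, tile_start=tile_start,
        tss_tiles=tss_tiles, flank_tiles=flank_tiles,
        peak_tiles=peak_tiles, decoy_peak_tiles=decoy_tiles,
        promoter_peak_tiles=promoter_peak_tiles,
        desert_marker_tiles=desert_marker_tiles,
        desert_uniform_tiles=desert_uniform,
        atac_ballast_tiles=atac_ballast,
        patient_tiles=patient_tiles, marker_body_tiles=marker_body_tiles,
        link_slots=link_slots, link_peak_tiles=link_peak_tiles,
        link_hosts=hosts, link_targets=link_targets,
        marker_genes=marker_genes, cnv_gene_ids=cnv_gene_ids,
        cnv_intervals=cnv_intervals, patient_genes=patient_genes,
        male_only=male_only, female_only=female_only,
        de_up=de_up, de_down=de_down, linked_de=linked_de,
        ballast=ballast, mito_genes=mito_genes,
    )


# ---------------------------------------------------------------------------
# Standardized group profiles
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mu = np.average(values, weights=weights)
    var = np.average((values - mu) ** 2, weights=weights)
    return (values - mu) / np.sqrt(var) if var > 0 else values - mu


def link_profiles(cfg: GeneratorConfig, hosts: list[str]) -> np.ndarray:
    """Per-link accessibility profile over the 8 (type, patient) ATAC groups.

    Row i is ``rho * y_hat_i + sqrt(1-rho^2) * c_hat_i`` (see module
    docstring); the confuser is the within-epithelium patient contrast,
    weight-orthogonalized against the host indicator.
    """
    w = np.array([cfg.type_props[t] / 2 for t, _ in ATAC_GROUPS])
    contrast = np.array(
        [(1.0 if s == "P1" else -1.0) if t == "epi_tumor" else 0.0 for t, s in ATAC_GROUPS]
    )
    rho = cfg.link_effect_r
    out = np.zeros((len(hosts), len(ATAC_GROUPS)))
    for i, h in enumerate(hosts):
        y = _standardize(np.array([1.0 if t == h else 0.0 for t, _ in ATAC_GROUPS]), w)
        c = contrast - (np.sum(w * contrast * y) / np.sum(w * y * y)) * y
        c = _standardize(c, w)
        out[i] = rho * y + np.sqrt(max(0.0, 1 - rho**2)) * c
    return out


def gene_type_multiplier(cfg: GeneratorConfig, host: str) -> dict[str, float]:
    """Expression multiplier per cell type for a link target gene."""
    props = np.array([cfg.type_props[t] for t in CELL_TYPES])
    y = _standardize(np.array([1.0 if t == host else 0.0 for t in CELL_TYPES]), props)
    mult = 1.0 + cfg.link_gene_delta * y
    return {t: float(max(m, 0.05)) for t, m in zip(CELL_TYPES, mult)}


# ---------------------------------------------------------------------------
# Truth container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    cell_table: pd.DataFrame        # barcode-indexed; rna + atac cells
    planted_links: pd.DataFrame     # peak_id, gene_id, host_type, target_metacell_r
    cnv_segments: list              # (sample, GenomicInterval, fold)
    de_genes: pd.DataFrame          # gene_id, direction, planted_log2fc
    sex_genes: dict                 # {"male_only": [...], "female_only": [...]}
    marker_genes: dict              # type -> gene ids (ships with the fixture)
    reference_enhancers: PeakSet    # synthetic normal-epithelium enhancer set
    layout: GenomeLayout

    @property
    def rna_cells(self) -> pd.DataFrame:
        return self.cell_table[self.cell_table["modality"] == "rna"]

    @property
    def atac_cells(self) -> pd.DataFrame:
        return self.cell_table[self.cell_table["modality"] == "atac"]


@dataclass
class Cohort:
    rna: CountsMatrix
    atac: CountsMatrix             # tile matrix
    genes: list
    peaks: PeakSet
    truth: SyntheticTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------

def _assign_cells(rng, cfg, sample, n, modality, type_props):
    types = list(type_props)
    probs = np.array([type_props[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    ct = rng.choice(types, size=n, p=probs)
    n_doub = int(round(cfg.doublet_rate * n))
    is_doub = np.zeros(n, bool)
    is_doub[rng.choice(n, size=n_doub, replace=False)] = True
    low_frac = cfg.rna_low_quality_frac if modality == "rna" else cfg.atac_low_quality_frac
    pool = np.flatnonzero(~is_doub)
    low = np.zeros(n, bool)
    low[rng.choice(pool, size=int(round(low_frac * n)), replace=False)] = True
    high_mito = np.zeros(n, bool)
    if modality == "rna":
        pool = np.flatnonzero(~is_doub & ~low)
        high_mito[rng.choice(pool, size=int(round(cfg.rna_high_mito_frac * n)), replace=False)] = True
    df = pd.DataFrame({
        "sample": sample, "cell_type": ct, "modality": modality,
        "is_doublet": is_doub, "planted_low_quality": low,
        "planted_high_mito": high_mito,
    })
    # partner type for doublets: a different type
    partner = []
    for i in range(n):
        if is_doub[i]:
            others = [t for t in types if t != ct[i]]
            partner.append(rng.choice(others))
        else:
            partner.append("")
    df["doublet_partner"] = partner
    df["is_tumor"] = (df["cell_type"] == "epi_tumor") & df["sample"].isin(MALE_SAMPLES)
    df["program"] = rng.uniform(0.0, 1.0, size=n)
    return df


# ---------------------------------------------------------------------------
# RNA generation
# ---------------------------------------------------------------------------

def _rna_base_weights(rng, cfg, layout) -> np.ndarray:
    n_nuc = len(layout.genes) - cfg.n_mito_genes
    w = np.exp(rng.normal(0.0, 0.7, size=n_nuc))
    w /= w.mean()                      # average weight 1 -> mean count depth/n
    idx = layout.gene_index
    # DE genes sit at moderate baseline: low enough for a detection-fraction
    # contrast (min.diff.pct filter), high enough that the +1-pseudocount
    # fold-change convention does not compress the planted fold below the
    # selection threshold
    low = 0.22
    for g in layout.de_up + layout.de_down + layout.linked_de:
        w[idx[g]] = low
    for g in layout.male_only + layout.female_only:
        w[idx[g]] = 0.5
    return w


def _rna_multiplier(cfg, layout, sample, cell_type) -> np.ndarray:
    """Unnormalized per-gene rate multiplier for one (sample, type) class."""
    n_nuc = len(layout.genes) - cfg.n_mito_genes
    m = np.ones(n_nuc)
    idx = layout.gene_index
    for t, ids in layout.marker_genes.items():
        if t == cell_type:
            for g in ids:
                m[idx[g]] *= cfg.marker_boost
    # link targets follow their host-type profile (same in every sample)
    for host, targets in zip(layout.link_hosts, layout.link_targets):
        tm = gene_type_multiplier(cfg, host)[cell_type]
        for g in targets:
            m[idx[g]] *= tm
    is_male = sample in MALE_SAMPLES
    if cell_type == "epi_tumor":
        if is_male:
            for g in layout.patient_genes.get(sample, []):
                m[idx[g]] *= cfg.patient_gene_boost
            for sample_c, fold, _ in cfg.cnv_segments:
                if sample_c == sample:
                    for g in layout.cnv_gene_ids[sample]:
                        m[idx[g]] *= fold
            for g in layout.de_up + layout.linked_de:
                m[idx[g]] *= 2.0 ** cfg.de_log2fc
            for g in layout.de_down:
                m[idx[g]] *= 2.0 ** (-cfg.de_log2fc)
    # hard-zero sex genes
    for g in layout.male_only:
        m[idx[g]] = m[idx[g]] if is_male else 0.0
    for g in layout.female_only:
        m[idx[g]] = 0.0 if is_male else m[idx[g]]
    return m


def _generate_rna(rng, cfg, layout, cells: pd.DataFrame) -> CountsMatrix:
    n_nuc = len(layout.genes) - cfg.n_mito_genes
    base = _rna_base_weights(rng, cfg, layout)
    classes = {}
    for s in ALL_SAMPLES:
        for t in CELL_TYPES:
            w = base * _rna_multiplier(cfg, layout, s, t)
            classes[(s, t)] = w
    # Compositional ballast: every cell's total weight is topped up to a
    # common target by the ballast genes, so housekeeping genes keep
    # identical expression *proportions* in every cell class and at every
    # program level. Without this, class-specific boost mass (and the
    # per-cell marker-intensity program) would imprint a deterministic
    # structure on every gene after depth normalization, which imputation
    # then amplifies into spurious peak-to-gene links.
    ballast_cols = np.array([layout.gene_index[g] for g in layout.ballast])
    marker_cols = {
        t: np.array([layout.gene_index[g] for g in layout.marker_genes[t]])
        for t in CELL_TYPES
    }
    # random program-response slope per housekeeping gene
    special = set(layout.ballast) | set(layout.male_only) | set(layout.female_only)
    special |= set(layout.de_up) | set(layout.de_down) | set(layout.linked_de)
    for ids in layout.marker_genes.values():
        special.update(ids)
    for ids in layout.cnv_gene_ids.values():
        special.update(ids)
    for ids in layout.patient_genes.values():
        special.update(ids)
    for targets in layout.link_targets:
        special.update(targets)
    slope = np.zeros(n_nuc)
    hk_cols = np.array(
        [i for i, g in enumerate(layout.genes[:n_nuc]) if g.gene_id not in special]
    )
    slope[hk_cols] = rng.uniform(-cfg.hk_state_slope, cfg.hk_state_slope, hk_cols.size)

    g_hi = cfg.program_lo + cfg.program_span
    t_target = max(
        w.sum() * (1.0 + 0.5 * cfg.hk_state_slope)
        + max(g_hi - 1.0, 0.0) * w[marker_cols[t]].sum()
        for (s, t), w in classes.items()
    )

    def cell_weights(sample, ctype, u):
        w = classes[(sample, ctype)] * (1.0 + slope * (u - 0.5))
        w[marker_cols[ctype]] *= cfg.program_lo + cfg.program_span * u
        w[ballast_cols] += (t_target - w.sum()) / ballast_cols.size
        return w
    n = len(cells)
    depth = np.exp(rng.normal(cfg.rna_depth_meanlog, cfg.rna_depth_sdlog, size=n))
    depth *= cells["sample"].map(cfg.sample_depth_factor).to_numpy()
    depth[cells["planted_low_quality"].to_numpy()] *= cfg.low_quality_depth_factor
    a, b = cfg.mito_beta
    mito_f = rng.beta(a, b, size=n)
    ah, bh = cfg.high_mito_beta
    hm = cells["planted_high_mito"].to_numpy()
    mito_f[hm] = rng.beta(ah, bh, size=int(hm.sum()))

    mito_w = np.exp(rng.normal(0.0, 0.5, size=cfg.n_mito_genes))
    mito_w /= mito_w.sum()

    mu = np.empty((n, len(layout.genes)))
    samples = cells["sample"].to_numpy()
    ctypes = cells["cell_type"].to_numpy()
    partners = cells["doublet_partner"].to_numpy()
    prog = cells["program"].to_numpy()
    for i in range(n):
        w = cell_weights(samples[i], ctypes[i], prog[i])
        if partners[i]:
            w = 0.5 * (w + cell_weights(samples[i], partners[i], prog[i]))
        p = w / w.sum()
        mu[i, :n_nuc] = depth[i] * (1 - mito_f[i]) * p
        mu[i, n_nuc:] = depth[i] * mito_f[i] * mito_w
    r = cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    # hard zeros stay hard (gamma of mu=0 is 0, but guard against fp dust)
    counts[mu == 0] = 0
    X = sp.csr_matrix(counts.astype(np.int64))
    return CountsMatrix(X, cells.index.tolist(), [g.gene_id for g in layout.genes],
                        "gene", cells)


# ---------------------------------------------------------------------------
# ATAC generation
# ---------------------------------------------------------------------------

def _atac_weights(cfg, layout, sample, cell_type, good: bool,
                  xprofiles: np.ndarray) -> np.ndarray:
    w = np.ones(layout.n_tiles)
    if not good:
        return w                      # low-quality barcodes: uniform debris
    w[layout.tss_tiles] *= cfg.tss_boost
    w[layout.decoy_peak_tiles] *= cfg.decoy_peak_boost
    w[layout.desert_uniform_tiles] *= cfg.decoy_peak_boost
    w[layout.desert_marker_tiles[cell_type]] *= cfg.atac_marker_boost
    w[layout.marker_body_tiles[cell_type]] *= cfg.atac_marker_boost
    if cell_type == "epi_tumor" and sample in layout.patient_tiles:
        w[layout.patient_tiles[sample]] *= cfg.atac_marker_boost
    gi = ATAC_GROUPS.index((cell_type, sample))
    link_mult = np.clip(1.0 + cfg.link_peak_gamma * xprofiles[:, gi], 0.05, None)
    w[layout.link_peak_tiles] = cfg.decoy_peak_boost * link_mult
    return w


def _generate_atac(rng, cfg, layout, cells: pd.DataFrame) -> CountsMatrix:
    xprof = link_profiles(cfg, layout.link_hosts)
    wclass = {
        (s, t): _atac_weights(cfg, layout, s, t, True, xprof)
        for s in MALE_SAMPLES
        for t in CELL_TYPES
    }
    uniform = _atac_weights(cfg, layout, "P1", CELL_TYPES[0], False, xprof)
    uniform = uniform / uniform.sum()
    # the program modulates half of each type's marker-gene body tiles (so
    # gene-activity projections track it) but not the desert marker tiles:
    # the LSI type clusters stay compact enough that graph clustering does
    # not fragment them along the gradient
    mod_tiles = {
        t: layout.marker_body_tiles[t][: len(layout.marker_body_tiles[t]) // 2]
        for t in CELL_TYPES
    }
    g_hi = cfg.program_lo + cfg.program_span
    t_target = max(
        w.sum() + max(g_hi - 1.0, 0.0) * w[mod_tiles[t]].sum()
        for (s, t), w in wclass.items()
    )
    ballast = layout.atac_ballast_tiles

    def cell_weights(sample, ctype, u):
        w = wclass[(sample, ctype)].copy()
        w[mod_tiles[ctype]] *= cfg.program_lo + cfg.program_span * u
        w[ballast] += (t_target - w.sum()) / ballast.size
        return w

    n = len(cells)
    depth = np.exp(rng.normal(cfg.atac_depth_meanlog, cfg.atac_depth_sdlog, size=n))
    depth *= cells["sample"].map(cfg.sample_depth_factor).to_numpy()
    low = cells["planted_low_quality"].to_numpy()
    depth[low] *= cfg.low_quality_depth_factor

    rows, cols, vals = [], [], []
    samples = cells["sample"].to_numpy()
    ctypes = cells["cell_type"].to_numpy()
    partners = cells["doublet_partner"].to_numpy()
    prog = cells["program"].to_numpy()
    for i in range(n):
        if low[i]:
            p = uniform
        else:
            w = cell_weights(samples[i], ctypes[i], prog[i])
            if partners[i]:
                w = 0.5 * (w + cell_weights(samples[i], partners[i], prog[i]))
            p = w / w.sum()
        c = rng.multinomial(int(depth[i]), p)
        nz = np.flatnonzero(c)
        rows.append(np.full(nz.size, i))
        cols.append(nz)
        vals.append(c[nz])
    X = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, layout.n_tiles), dtype=np.int64,
    )
    features = [
        f"{c}:{s}-{s + cfg.tile_width}"
        for c, s in zip(layout.tile_chrom, layout.tile_start)
    ]
    return CountsMatrix(X, cells.index.tolist(), features, "tile", cells)


# ---------------------------------------------------------------------------
# Peaks, reference enhancers, truth
# ---------------------------------------------------------------------------

def _tile_interval(layout, cfg, t: int, score: float | None = None) -> GenomicInterval:
    return GenomicInterval(
        str(layout.tile_chrom[t]), int(layout.tile_start[t]),
        int(layout.tile_start[t]) + cfg.tile_width, score=score,
    )


def _nominal_peaks(cfg, layout) -> PeakSet:
    return PeakSet(
        [_tile_interval(layout, cfg, t) for t in layout.peak_tiles],
        fixed_width=cfg.tile_width,
    )


def _reference_enhancers(rng, cfg, layout) -> PeakSet:
    """Synthetic stand-in for a normal-mammary-epithelium enhancer BED.

    Covers a few planted cancer peaks (so the subtraction is non-trivial),
    a slice of the lineage peaks, and random desert intervals. One interval
    is exactly adjacent (half-open) to a cancer peak to pin down adjacency
    semantics.
    """
    ivs = []
    epi_idx = [i for i, h in enumerate(layout.link_hosts) if h == "epi_tumor"]
    lineage_idx = [i for i, h in enumerate(layout.link_hosts) if h != "epi_tumor"]
    covered = epi_idx[: cfg.n_reference_overlap_cancer]
    for j, i in enumerate(covered):
        t = layout.link_peak_tiles[i]
        start = int(layout.tile_start[t])
        # one of them overlaps by exactly 1 bp
        if j == 0:
            ivs.append(GenomicInterval("chr1", start - 699, start + 1, id=f"ref_cancer_{j}"))
        else:
            ivs.append(GenomicInterval("chr1", start - 100, start + 600, id=f"ref_cancer_{j}"))
    # adjacency control: touches the next epi peak without overlap
    if len(epi_idx) > cfg.n_reference_overlap_cancer:
        t = layout.link_peak_tiles[epi_idx[cfg.n_reference_overlap_cancer]]
        start = int(layout.tile_start[t])
        ivs.append(GenomicInterval("chr1", start - 700, start, id="ref_adjacent"))
    for j, i in enumerate(lineage_idx[: cfg.n_reference_overlap_lineage]):
        t = layout.link_peak_tiles[i]
        start = int(layout.tile_start[t])
        ivs.append(GenomicInterval("chr1", start - 100, start + 600, id=f"ref_lineage_{j}"))
    lo = 2_250_000
    hi = cfg.chr2_len - 1_000
    for j in range(cfg.n_reference_random):
        s = int(rng.integers(lo, hi - 700))
        ivs.append(GenomicInterval("chr2", s, s + 700, id=f"ref_rand_{j}"))
    return PeakSet(ivs)


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate the matched cohort. Deterministic given ``cfg.rng_seed``."""
    cfg.validate()
    layout = build_layout(cfg)
    rng = np.random.default_rng(cfg.rng_seed)

    tables = []
    for s in ALL_SAMPLES:
        props = dict(cfg.type_props)
        if s == "F":
            props = {"epi_tumor": 0.5, "macrophage": 0.2, "fibroblast": 0.2, "endothelial": 0.1}
        df = _assign_cells(rng, cfg, s, cfg.n_rna_cells_per_sample, "rna", props)
        df.index = [f"{s}_RNA_{i:05d}" for i in range(len(df))]
        tables.append(df)
    for s in MALE_SAMPLES:
        df = _assign_cells(rng, cfg, s, cfg.n_atac_cells_per_sample, "atac", cfg.type_props)
        df.index = [f"{s}_ATAC_{i:05d}" for i in range(len(df))]
        tables.append(df)
    cell_table = pd.concat(tables)
    cell_table.index.name = "barcode"

    rna = _generate_rna(rng, cfg, layout, cell_table[cell_table["modality"] == "rna"])
    atac = _generate_atac(rng, cfg, layout, cell_table[cell_table["modality"] == "atac"])
    peaks = _nominal_peaks(cfg, layout)
    reference = _reference_enhancers(rng, cfg, layout)

    link_rows = []
    peak_ids = {
        i: _tile_interval(layout, cfg, t).default_id()
        for i, t in enumerate(layout.link_peak_tiles)
    }
    for i, (host, targets) in enumerate(zip(layout.link_hosts, layout.link_targets)):
        for g in targets:
            link_rows.append((peak_ids[i], g, host, cfg.link_effect_r))
    planted_links = pd.DataFrame(
        link_rows, columns=["peak_id", "gene_id", "host_type", "target_metacell_r"]
    )

    de_rows = (
        [(g, "up", cfg.de_log2fc) for g in layout.de_up + layout.linked_de]
        + [(g, "down", -cfg.de_log2fc) for g in layout.de_down]
    )
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "direction", "planted_log2fc"])

    truth = SyntheticTruth(
        cell_table=cell_table,
        planted_links=planted_links,
        cnv_segments=[(s, layout.cnv_intervals[s], fold) for s, fold, _ in cfg.cnv_segments],
        de_genes=de_genes,
        sex_genes={"male_only": layout.male_only, "female_only": layout.female_only},
        marker_genes=layout.marker_genes,
        reference_enhancers=reference,
        layout=layout,
    )
    return Cohort(rna=rna, atac=atac, genes=layout.genes, peaks=peaks,
                  truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Motif fixture (sequences + MEME) for the occupancy stage
# ---------------------------------------------------------------------------

_MOTIF_CONSENSI = {"epi": "TGACGTCA", "stromal": "CACCTGGA"}


def motif_fixture(cohort: Cohort, rng_seed: int | None = None):
    """Random enhancer sequences with the epithelial motif consensus planted
    in cancer-link peaks and a stromal consensus in lineage-link peaks.

    Returns (sequences: dict peak_id -> str, meme_text: str,
    motif_tf: dict motif_id -> gene_id). Motif ids are the gene ids of an
    epithelial and a fibroblast marker gene so TF-expression ranking can be
    exercised against the cohort's own RNA.
    """
    cfg = cohort.config
    layout = cohort.truth.layout
    rng = np.random.default_rng(cfg.rng_seed + 977 if rng_seed is None else rng_seed)
    bases = np.array(list("ACGT"))
    seqs = {}
    for i, t in enumerate(layout.link_peak_tiles):
        pid = _tile_interval(layout, cfg, t).default_id()
        seq = list(rng.choice(bases, size=cfg.tile_width))
        motif = _MOTIF_CONSENSI["epi" if layout.link_hosts[i] == "epi_tumor" else "stromal"]
        for off in (60, 300):
            seq[off : off + len(motif)] = list(motif)
        seqs[pid] = "".join(seq)
    epi_tf = layout.marker_genes["epi_tumor"][0]
    stromal_tf = layout.marker_genes["fibroblast"][0]
    motif_tf = {epi_tf: epi_tf, stromal_tf: stromal_tf}
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
        "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
    ]
    for name, cons in zip([epi_tf, stromal_tf], _MOTIF_CONSENSI.values()):
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(cons)} nsites= 100 E= 0"
        )
        for ch in cons:
            row = {b: 0.01 for b in "ACGT"}
            row[ch] = 0.97
            lines.append(" ".join(f"{row[b]:.3f}" for b in "ACGT"))
        lines.append("")
    return seqs, "\n".join(lines) + "\n", motif_tf


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_fixture(cohort: Cohort, directory: str | os.PathLike, force: bool = False) -> None:
    """Write the cohort as on-disk fixture files (MTX pairs, BED, TSVs,
    GMT, FASTA, MEME). Refuses a non-empty directory unless ``force``.
    """
    directory = os.fspath(directory)
    if os.path.isdir(directory) and os.listdir(directory) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")
    os.makedirs(directory, exist_ok=True)
    write_counts_mtx(cohort.rna, os.path.join(directory, "rna"))
    write_counts_mtx(cohort.atac, os.path.join(directory, "atac"))
    write_bed(cohort.peaks, os.path.join(directory, "peaks.bed"))
    write_bed(cohort.truth.reference_enhancers,
              os.path.join(directory, "reference_enhancers.bed"))
    write_gene_models(cohort.genes, os.path.join(directory, "genes.tsv"))

    t = cohort.truth
    t.cell_table.to_csv(os.path.join(directory, "truth_cells.tsv"), sep="\t")
    t.planted_links.to_csv(os.path.join(directory, "truth_links.tsv"), sep="\t", index=False)
    t.de_genes.to_csv(os.path.join(directory, "truth_de_genes.tsv"), sep="\t", index=False)
    rows = [("male_only", g) for g in t.sex_genes["male_only"]] + [
        ("female_only", g) for g in t.sex_genes["female_only"]
    ]
    pd.DataFrame(rows, columns=["side", "gene_id"]).to_csv(
        os.path.join(directory, "truth_sex_genes.tsv"), sep="\t", index=False
    )
    rows = [(ct, g) for ct, ids in t.marker_genes.items() for g in ids]
    pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(
        os.path.join(directory, "markers.tsv"), sep="\t", index=False
    )
    with open(os.path.join(directory, "gene_sets.gmt"), "w") as fh:
        up = t.de_genes.loc[t.de_genes["direction"] == "up", "gene_id"].tolist()
        fh.write("SET_MALE_UP\tplanted male-up genes\t" + "\t".join(up) + "\n")
        fh.write("SET_EPI_MARKERS\tepithelial markers\t" + "\t".join(t.marker_genes["epi_tumor"]) + "\n")
        hk = [g.gene_id for g in cohort.genes[:50]]
        fh.write("SET_DECOY\thousekeeping decoy\t" + "\t".join(hk) + "\n")

    seqs, meme, motif_tf = motif_fixture(cohort)
    with open(os.path.join(directory, "enhancer_sequences.fa"), "w") as fh:
        for pid, s in seqs.items():
            fh.write(f">{pid}\n{s}\n")
    with open(os.path.join(directory, "motifs.meme"), "w") as fh:
        fh.write(meme)
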