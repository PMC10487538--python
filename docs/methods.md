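# Methods

This note documents the models, parameter choices and numerical decisions
behind `screlink`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic cohort does and does not
emulate.

## Pipeline overview

The pipeline mirrors the standard matched-multiome tumor workflow:

1. **QC** per sample and modality. RNA outliers are defined by strict
   inequalities (UMIs < floor, genes < floor, mitochondrial % > ceiling), so
   boundary cells are retained. ATAC uses a two-component Gaussian-mixture
   cutoff on log10 fragments plus a tile-based TSS-enrichment proxy
   (`log10(score+1) ≥ 0.9`). Doublets are scored as the fraction of
   simulated doublets (averaged random cell pairs) among a cell's nearest
   neighbors in a reduced space; the removal budget is
   `filter_ratio × expected doublets` (rate 8 per 1,000 cells, scaling with
   cohort size), mirroring the filter-ratio contract of droplet doublet
   tools.
2. **RNA reduction**: log-normalization (`ln(1 + 1e4·x/total)`), top-2000
   genes by standardized variance with a degree-2 polynomial mean–variance
   trend (a dependency-free stand-in for the loess "vst" — monotone-
   equivalent ranking on this data), per-gene scaling with mitochondrial-
   fraction regression, PCA (50 components, 30 used), per-sample centering
   in the reduced space as the batch step, shared-nearest-neighbor graph +
   modularity clustering at resolution 0.8, and cluster-majority cell
   typing from marker-gene scores.
3. **CNV inference and malignancy calls** (per patient; immune +
   endothelial clusters as reference) — see below.
4. **ATAC reduction**: TF-IDF (`log(1 + tf·idf·1e4)`) and two-round
   iterative LSI on the most accessible / most variable tiles, dropping
   components with |correlation| > 0.75 against log10 depth.
5. **Label transfer**: the query gene-activity matrix (gene-body counts
   with an exponentially decaying promoter extension) is projected with the
   reference PCA loadings; labels come from a k = 15 nearest-neighbor vote
   (same patient only), cells with prediction score ≤ 0.5 are excluded.
   Two refinements proved necessary (see "Imputation bias" below):
   query/reference centroids are aligned per provisional label before the
   final pass, and the imputed expression uses usage-balanced
   nearest-neighbor matching on a depth-downsampled reference.
6. **Peaks and links**: per-cell-type pseudobulk peak calls (a naive
   thresholder over tile means, standing in for a peak caller on desk-scale
   fixtures) merged by iterative overlap removal into a universal
   fixed-width set; peaks classified promoter > exonic > intronic > distal
   (promoter window −2000/+100 around the strand-aware TSS); metacells of
   k = 100 cells (farthest-point seeds, pairwise overlap ≤ 80, `⌈n/20⌉`
   groups capped at 500); Pearson correlation of metacell peak
   accessibility vs aggregated imputed expression for all same-chromosome
   pairs within 250 kb; p from the t-transform with n = number of
   metacells; BH-FDR across all tested pairs; headline filter `r ≥ 0.45`,
   `FDR ≤ 1e-12`, distal only; k-means (k = 5) on row-scaled per-type
   profiles with an argmax cell-type enrichment label per cluster.
7. **Enhancer analysis**: tumor-cluster peaks partitioned against a
   normal-epithelium enhancer BED by ≥ 1 bp overlap (half-open adjacency is
   not an overlap); regulatory load compared by two-sided rank-sum;
   upregulated linked genes selected at `log2FC > 1` and `padj < 0.01`;
   super-enhancer candidates are genes with > 5 mutually correlated
   (median pairwise metacell r ≥ 0.45), genomically clustered (span ≤
   150 kb) distal links — the span and pairwise-r parameters are this
   package's own operationalization of a qualitative concept.
8. **DE and motifs**: two-sided rank-sum DE with detection-fraction and
   fold-change pre-filters and per-group downsampling to 500 cells
   (fold change is the de-logged-mean-plus-one convention of the
   single-cell ecosystem); hypergeometric gene-set enrichment (BH q ≤
   0.01); PWM scanning with exact p-values from a dynamic program over
   integer-discretized log-odds scores (granularity 1/1000 bit), BH
   q-values over scanned windows, hypergeometric target-vs-background motif
   containment, and ranking of significant motifs by summed malignant-cell
   TF expression.

All stages are seeded; with a fixed seed and one thread the pipeline's
output tables are byte-identical across runs.

## The malignancy classifier

Expression residuals are computed as in expression-based CNV callers:
genes with mean normalized expression < 0.1 are dropped, residuals are
centered on the reference-cell mean, smoothed with a 101-gene moving
average along the genome, re-centered per cell, and denoised by zeroing
residuals inside ±1.5 reference SDs. Two design choices depart from the
common recipe, both forced by calibration against CNV-free cohorts:

* **Per-chromosome (not global) median centering.** A cell type's
  expression-program load differs between chromosomes; after depth
  normalization this produces chromosome-scale residual plateaus that are
  indistinguishable from whole-chromosome CNVs. Centering each chromosome
  removes the plateau; the cost is that true whole-chromosome events are
  invisible to this variant (a documented limitation — the planted events
  are sub-chromosomal).
* **A studentized run-scale matched filter as the CNV score.** Copy-number
  events are *contiguous* runs of genes; expression programs are scattered
  across the genome. The score is the largest absolute running mean of the
  per-chromosome-centered residuals over ~150 genome-ordered genes,
  restricted to genes within 3 robust SDs of that cell (sparse program and
  bursty-gene deviations are dropped), and divided by the cell's own
  residual scale. Studentization makes the statistic dimensionless, so
  CNV-free epithelial cells score like reference cells regardless of their
  program load or depth.

Calls use a two-tier gate calibrated on simulated CNV-free and
CNV-bearing cohorts (seeds disjoint from the test seeds): *tumor* requires
score above an outlier fence over the reference scores
(`median + 3 × (q75 − median)`) with correlation > 0.4 to the mean profile
of the top-5% scoring cells, or score above 80% of the fence with
correlation > 0.7; and at least 20 passing cells (a tumor is a population,
not isolated outliers). *Normal* requires score at or below the reference
median with correlation ≤ 0.4; everything else is unassigned, and reference
cells are never called tumor. A plain reference quantile cannot give a
clean null — a fixed fraction of CNV-free cells exceeds any
within-distribution quantile by construction — which is why the fence is an
outlier rule. The operating point is flat over a wide range (the null stays
empty for fence multipliers 3–6), so the calibration is not knife-edge.

## The synthetic cohort

The generator is the package's study-condition definition, not a test
convenience; its defaults are chosen once as a realistic desk-scale cohort.

**Scale.** Two male "patients" (P1, P2) with 2,000 RNA and 1,500 ATAC cells
each, plus a female comparator sample of 2,000 RNA cells; a three-
chromosome genome (~3,200 genes, 32,000 × 500-bp tiles) defined entirely by
the emitted gene TSV. The RNA reference is deliberately larger than the
ATAC cohort (as in the underlying study designs): with small reference
pools, per-(type, patient) sampling offsets — an artifact of scale, not of
the method — would dominate the imputed expression.

**Cells.** Four types (malignant epithelium 40%, macrophages 25%,
fibroblasts 20%, endothelium 15%), negative-binomial RNA counts
(dispersion r = 5, var/mean ≈ 2 at typical depth, matching droplet UMI
data) with log-normal depths (median ~12,000 UMIs; ATAC ~6,000 fragments)
and per-sample depth factors as the only batch effect; Beta-distributed
mitochondrial fractions; planted doublets (averaged cross-type pairs, 1% —
matched to droplet doublet rates at this loading), low-quality cells (8%
depth) and high-mitochondrial cells.

**Programs.** Each type has 80 marker genes at 2.5× (ATAC: marker tiles at
6×), each patient's tumor cells 90 patient-specific genes at 2.2× plus
patient-specific accessible tiles strong enough that the epithelial
compartment separates by patient, as matched tumor scATAC does. Every cell
carries a continuous activation program u ~ U(0,1) that scales its marker
intensity (0.6–1.4×) in both modalities, and every housekeeping gene
responds to u with a random slope (±0.6 relative): real within-type
heterogeneity, without which finite-pool sampling noise would be the only
within-type variation and every frozen offset would masquerade as signal.
Effects are moderate and spread over many genes deliberately — a contiguous
block of few large-effect genes is indistinguishable from a CNV by any
expression-based method, so special genes are *scattered* across chr2 and
the planted CNV segments are positional runs (250 genes at 1.5× per
patient) whose fold applies to whatever genes they contain.

**Mass neutrality.** Depth normalization makes expression compositional:
any class- or program-dependent boost mass deflates every other gene's
proportion, imprinting a spurious deterministic structure on all
"unchanged" genes. The generator therefore tops every cell's total weight
up to a common target through dedicated ballast genes (RNA) and ballast
tiles (ATAC), so housekeeping proportions are exactly class- and
program-invariant.

**Links.** 70 planted enhancer peaks on chr1 (one per 75-kb locus,
same-host-type loci ≥ 300 kb apart) carry 100 peak-to-gene links: all
epithelial peaks and a subset of lineage peaks target two genes, the rest
one — the planted regulatory-load contrast. A peak's accessibility profile
over the eight (type, patient) classes is
`ρ·ŷ + sqrt(1−ρ²)·ĉ`, where `ŷ` is the standardized host-type indicator
of its target gene, `ĉ` a standardized within-epithelium patient contrast
orthogonalized against `ŷ` (a profile no gene follows), and ρ = 0.7 the
target metacell correlation. Coupling is at the population level by
necessity: the pipeline correlates accessibility against expression
imputed from *different* cells, so a per-cell latent would be averaged away
by the method under test. Decoy peaks (~5,000) live on chr3 among
housekeeping genes only; a decoy in cis of a cell-type-specific target
would genuinely covary with it — that is precisely how the method works —
so keeping decoys out of cis range is what makes truth-based precision
well-defined. Twenty epithelial targets additionally carry the
male-vs-female fold (planted log2FC 2.0 at moderate baseline, so the
+1-pseudocount fold-change convention still clears the selection threshold
of 1.0), making them the planted analog of upregulated cancer-enhancer
genes. A synthetic "normal mammary epithelium" BED covers a few cancer
peaks (including one by exactly 1 bp, and one adjacent without overlap, to
pin the subtraction semantics), a slice of the lineage peaks, and random
desert intervals.

**What the generator does not emulate.** Read-level structure and fragment
files; realistic gene/peak density and distance distributions (loci are
idealized and isolated); batch effects beyond a per-sample depth factor;
ambient RNA; cell-cycle structure; the empirical effect-size distribution
of real enhancer–gene couplings (no published distribution exists; the coupling
strength is a config knob). Consequently, passing tests demonstrate that
the implementation recovers known structure under the stated statistical
model — not that the thresholds would achieve the same operating point on
real tissue.

## Imputation bias (why label transfer has two extra steps)

Imputed expression is the lever through which subtle biases become false
enhancer–gene links, because metacell aggregation suppresses independent
noise but preserves anything systematic. Three mechanisms, found and
eliminated during development, are worth recording:

1. **Compositional class structure** — solved in the generator by mass
   neutrality (above); in real data this is the familiar library-
   composition effect.
2. **Hub reuse** — plain k-NN imputation uses a few central reference
   cells hundreds of times while never touching a quarter of the pool; any
   chance covariance between that frozen usage pattern and a gene's values
   becomes a systematic per-type bias. The imputation assignment therefore
   caps per-reference-cell reuse (usage-balanced matching, `impute_k = 1`
   by default), which keeps usage nearly uniform while preserving
   locality.
3. **Selection-by-value** — deeper reference cells have fewer dropouts and
   thus higher log-normalized values for *every* gene; any selection bias
   toward them shifts the imputed matrix. The imputation reference is
   binomially thinned to a common depth (20th percentile) so that equal
   profiles imply equal dropout.

With these in place the permuted-label null is empty and planted-link
precision is ~1 at the published thresholds.

## Numerical conventions

* Coordinates are 0-based half-open everywhere; 1-based inclusive only at
  the printed-text boundary. Published browser-style enhancer coordinates
  whose width equals the tile width are ingested verbatim
  (`one_based=False`).
* Sorting ties break by (chrom, start, end, id); peak ids default to
  `chrom:start-end`; all ingest is strict (no silent clamping).
* PCA/SVD use a deterministic sign convention (largest-magnitude loading
  positive). k-means uses 10 seeded restarts; graph clustering is seeded
  Leiden on a Jaccard-weighted SNN graph.
* The rank-sum test uses the tie-corrected normal approximation with
  continuity correction, or the exact null distribution (dynamic program
  equivalent to full enumeration) for tie-free samples up to n = 25 per
  group; two-sided exact p is `P(|W − E W| ≥ |w − E W|)`.
* Zero-variance vectors are skipped and counted in correlation; degenerate
  GMM fits (component separation < 2 pooled SDs or weight < 0.05) fall
  back to a configured floor; BH is the step-up rule clipped at 1,
  returned in input order.
* Desk-scale fixture thresholds: the RNA QC gene floor is 800 (not the
  patient-scale 2,000) because the synthetic genome only has ~3,200 genes;
  all other thresholds keep their patient-scale values.

## Known limitations

* Whole-chromosome CNVs are invisible to the per-chromosome-centered
  classifier; the correlation axis of the malignancy scatter depends on a
  top-5% heuristic that assumes tumor cells are a minority-or-more of the
  sample.
* The cross-modal projection is a linear stand-in for anchor-based
  integration; it relies on shared marker structure and per-type centroid
  alignment, and will degrade if query and reference manifolds differ in
  shape, not just offset.
* Statistical power at `FDR ≤ 1e-12` depends on the metacell count; the
  `⌈n/20⌉` default trades recall for selectivity, and treating overlapping
  metacells as independent samples overstates significance (as it does in
  the underlying methodology).
* The super-enhancer rule is a declared operationalization; its span and
  co-correlation defaults are conventions, not measurements.
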