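"""Peak merging, annotation, metacells and peak-to-gene correlation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from screlink.io_intervals import CountsMatrix, GeneModel, GenomicInterval, PeakSet
from screlink.linkage import (
    MetacellGrouping,
    aggregate_metacell_means,
    aggregate_metacells,
    annotate_peak,
    annotate_peaks,
    correlate_peak_gene,
    filter_links,
    iterative_overlap_merge,
    kmeans_links,
    make_metacells,
    peak_matrix_from_tiles,
)
from screlink.reduce_cluster import ReducedSpace


def _iv(chrom, start, end, score=None, id=None):
    return GenomicInterval(chrom, start, end, id=id, score=score)


class TestIterativeOverlapMerge:
    def test_disjoint_peaks_all_kept(self):
        ps = PeakSet([_iv("chr1", 0, 500, 3.0), _iv("chr1", 1000, 1500, 1.0)],
                     fixed_width=500)
        out = iterative_overlap_merge([ps])
        assert len(out) == 2

    def test_overlapping_keeps_best_score(self):
        ps = PeakSet([
            _iv("chr1", 0, 500, 10.0), _iv("chr1", 250, 750, 5.0)
        ], fixed_width=500)
        out = iterative_overlap_merge([ps])
        assert len(out) == 1 and out[0].start == 0

    def test_chain_keeps_first_and_third(self):
        # A-B overlap, B-C overlap, A-C disjoint; scores 3 > 2 > 1 -> {A, C}
        a = _iv("chr1", 0, 500, 3.0)
        b = _iv("chr1", 400, 900, 2.0)
        c = _iv("chr1", 800, 1300, 1.0)
        out = iterative_overlap_merge([PeakSet([a, b, c], fixed_width=500)])
        assert [(iv.start, iv.end) for iv in out] == [(0, 500), (800, 1300)]

    def test_duplicate_calls_across_clusters_deduped(self):
        p1 = PeakSet([_iv("chr1", 0, 500, 4.0)], fixed_width=500)
        p2 = PeakSet([_iv("chr1", 0, 500, 9.0)], fixed_width=500)
        out = iterative_overlap_merge([p1, p2])
        assert len(out) == 1 and out[0].score == 9.0

    def test_unscored_peak_rejected(self):
        ps = PeakSet([_iv("chr1", 0, 500)])
        with pytest.raises(ValueError, match="score"):
            iterative_overlap_merge([ps])


class TestAnnotatePeak:
    genes = [
        GeneModel("g+", GenomicInterval("chr1", 10_000, 20_000, id="g+"), "+"),
        GeneModel("g-", GenomicInterval("chr1", 50_000, 60_000, id="g-"), "-"),
    ]

    def test_peak_over_tss_is_promoter(self):
        assert annotate_peak(_iv("chr1", 9_800, 10_300), self.genes) == "promoter"

    def test_strand_aware_promoter_on_minus_gene(self):
        # '-' gene TSS at 59,999; promoter extends upstream to 61,999
        assert annotate_peak(_iv("chr1", 61_000, 61_500), self.genes) == "promoter"

    def test_peak_inside_body_is_intronic(self):
        assert annotate_peak(_iv("chr1", 15_000, 15_500), self.genes) == "intronic"

    def test_exon_table_promotes_to_exonic(self):
        exons = {"g+": [GenomicInterval("chr1", 14_900, 15_200)]}
        assert annotate_peak(_iv("chr1", 15_000, 15_500), self.genes,
                             exons=exons) == "exonic"

    def test_far_peak_is_distal(self):
        assert annotate_peak(_iv("chr1", 120_000, 120_500), self.genes) == "distal"


class TestMetacells:
    def _space(self, rng, n=300, d=5):
        return ReducedSpace(rng.normal(size=(n, d)), "lsi", np.zeros(d),
                            np.arange(d), barcodes=[str(i) for i in range(n)])

    def test_singleton_groups_disjoint(self, rng):
        space = self._space(rng, n=50)
        grp = make_metacells(space, k=1, n_groups=20, max_shared=0, seed=0)
        flat = np.concatenate(grp.groups)
        assert len(flat) == len(set(flat.tolist()))

    def test_every_group_has_exactly_k_members(self, rng):
        space = self._space(rng)
        grp = make_metacells(space, k=40, n_groups=15, seed=0)
        assert all(len(g) == 40 for g in grp.groups)

    def test_pairwise_overlap_cap_holds_vs_oracle(self, rng):
        space = self._space(rng)
        grp = make_metacells(space, k=50, n_groups=20, max_shared=25, seed=0)
        sets = [set(g.tolist()) for g in grp.groups]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert len(sets[i] & sets[j]) <= 25

    def test_k_larger_than_n_rejected(self, rng):
        space = self._space(rng, n=10)
        with pytest.raises(ValueError):
            make_metacells(space, k=20)


class TestAggregation:
    def test_singleton_groups_identity_sums(self, rng):
        X = rng.poisson(4.0, size=(6, 8))
        grp = MetacellGrouping([np.array([i]) for i in range(6)], k=1, max_shared=0)
        agg = aggregate_metacells(sp.csr_matrix(X), grp, lognorm=False)
        assert np.allclose(agg, X)

    def test_group_sums_equal_member_sums(self, rng):
        X = rng.poisson(4.0, size=(10, 8))
        groups = [np.array([0, 1, 2]), np.array([2, 5, 9])]
        grp = MetacellGrouping(groups, k=3, max_shared=2)
        agg = aggregate_metacells(sp.csr_matrix(X), grp, lognorm=False)
        for gi, g in enumerate(groups):
            assert np.allclose(agg[gi], X[g].sum(axis=0))

    def test_sparse_and_dense_agree(self, rng):
        X = rng.poisson(2.0, size=(12, 6))
        grp = MetacellGrouping([np.array([0, 3, 4]), np.array([1, 2, 5])], 3, 2)
        a = aggregate_metacells(sp.csr_matrix(X), grp, lognorm=True)
        b = aggregate_metacells(X, grp, lognorm=True)
        assert np.allclose(a, b)

    def test_mean_aggregation(self, rng):
        X = rng.normal(size=(9, 4))
        grp = MetacellGrouping([np.array([0, 1, 2])], 3, 0)
        out = aggregate_metacell_means(X, grp)
        assert np.allclose(out[0], X[:3].mean(axis=0))


def _linkage_setup(rng, n_meta=40, n_peaks=12, n_genes=6):
    genes = [
        GeneModel(f"g{i}", GenomicInterval("chr1", i * 40_000, i * 40_000 + 2_000,
                                           id=f"g{i}"), "+")
        for i in range(n_genes)
    ]
    peaks = PeakSet([
        _iv("chr1", 10_000 + i * 20_000, 10_500 + i * 20_000, id=f"p{i}")
        for i in range(n_peaks)
    ])
    A = rng.normal(size=(n_meta, n_peaks))
    G = rng.normal(size=(n_meta, n_genes))
    return genes, peaks, A, G


class TestCorrelatePeakGene:
    def test_identical_vectors_r_one(self, rng):
        genes, peaks, A, G = _linkage_setup(rng)
        G[:, 0] = A[:, 0]
        links = correlate_peak_gene(A, G, peaks, genes)
        row = links[(links.peak_id == "p0") & (links.gene_id == "g0")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_r_and_p_match_scipy_oracle(self, rng):
        genes, peaks, A, G = _linkage_setup(rng, n_meta=30)
        links = correlate_peak_gene(A, G, peaks, genes)
        assert len(links) >= 50
        gpos = {g.gene_id: i for i, g in enumerate(genes)}
        ppos = {p: i for i, p in enumerate(peaks.ids)}
        for row in links.head(100).itertuples():
            r, p = stats.pearsonr(A[:, ppos[row.peak_id]], G[:, gpos[row.gene_id]])
            assert row.r == pytest.approx(r, abs=1e-10)
            assert row.p == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_zero_variance_pairs_skipped(self, rng):
        genes, peaks, A, G = _linkage_setup(rng)
        A[:, 2] = 1.0
        links = correlate_peak_gene(A, G, peaks, genes)
        assert not (links.peak_id == "p2").any()
        assert links.attrs["n_skipped"] > 0

    def test_distance_window_respected(self, rng):
        genes, peaks, A, G = _linkage_setup(rng)
        links = correlate_peak_gene(A, G, peaks, genes, max_dist=50_000)
        assert (links["distance_bp"].abs() <= 50_000).all()

    def test_bh_monotone_and_bounded_below_by_p(self, rng):
        genes, peaks, A, G = _linkage_setup(rng)
        links = correlate_peak_gene(A, G, peaks, genes).sort_values("p")
        fdr = links["fdr"].to_numpy()
        p = links["p"].to_numpy()
        assert (np.diff(fdr) >= -1e-12).all()
        assert (fdr >= p - 1e-15).all()


class TestFilterLinks:
    def _frame(self):
        return pd.DataFrame({
            "peak_id": ["a", "b", "c", "d"],
            "gene_id": ["g"] * 4,
            "r": [0.45, 0.44, 0.9, 0.9],
            "p": [1e-20] * 4,
            "fdr": [1e-13, 1e-13, 1e-13, 1e-5],
            "distance_bp": [100] * 4,
            "peak_class": ["distal", "distal", "promoter", "distal"],
        })

    def test_boundary_r_kept_promoter_excluded_weak_fdr_dropped(self):
        out = filter_links(self._frame())
        assert list(out["peak_id"]) == ["a"]

    def test_empty_input(self):
        out = filter_links(self._frame().iloc[:0])
        assert out.empty


class TestKmeansLinks:
    def test_five_blocks_perfectly_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        types = [f"t{i}" for i in range(5)]
        rows = []
        truth = []
        peak_prof, gene_prof = {}, {}
        for b in range(5):
            for j in range(20):
                pid, gid = f"p{b}_{j}", f"g{b}_{j}"
                rows.append((pid, gid))
                truth.append(b)
                prof = np.full(5, 0.2)
                prof[b] = 3.0
                peak_prof[pid] = prof + rng.normal(0, 0.01, 5)
                gene_prof[gid] = prof + rng.normal(0, 0.01, 5)
        links = pd.DataFrame(rows, columns=["peak_id", "gene_id"])
        pp = pd.DataFrame(peak_prof, index=types).T
        gp = pd.DataFrame(gene_prof, index=types).T
        out = kmeans_links(links, pp, gp, k=5, seed=0)
        assert adjusted_rand_score(truth, out["kmeans_cluster"]) == 1.0
        # enrichment labels point to the planted type
        for b, cl in zip(truth, out["kmeans_cluster"]):
            assert out["cluster_celltype"][out["kmeans_cluster"] == cl].iloc[0] == types[b]

    def test_k_one_single_cluster(self, rng):
        links = pd.DataFrame({"peak_id": ["p1", "p2"], "gene_id": ["g1", "g2"]})
        pp = pd.DataFrame(rng.normal(size=(2, 3)), index=["p1", "p2"],
                          columns=list("abc"))
        gp = pd.DataFrame(rng.normal(size=(2, 3)), index=["g1", "g2"],
                          columns=list("abc"))
        out = kmeans_links(links, pp, gp, k=1, seed=0)
        assert set(out["kmeans_cluster"]) == {1}

    def test_row_scaling_affine_invariant(self, rng):
        links = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(10)],
            "gene_id": [f"g{i}" for i in range(10)],
        })
        base = rng.normal(size=(10, 4))
        pp1 = pd.DataFrame(base, index=links["peak_id"], columns=list("wxyz"))
        pp2 = pd.DataFrame(base * 7.0 + 3.0, index=links["peak_id"],
                           columns=list("wxyz"))
        gp = pd.DataFrame(rng.normal(size=(10, 4)), index=links["gene_id"],
                          columns=list("wxyz"))
        a = kmeans_links(links, pp1, gp, k=3, seed=0)["kmeans_cluster"]
        b = kmeans_links(links, pp2, gp, k=3, seed=0)["kmeans_cluster"]
        assert (a == b).all()


class TestPeakMatrix:
    def test_counts_summed_over_overlapping_tiles(self, rng):
        tiles = CountsMatrix(
            sp.csr_matrix(np.array([[2, 3, 5, 7]])),
            ["c0"],
            [f"chr1:{j * 500}-{(j + 1) * 500}" for j in range(4)],
        )
        peaks = PeakSet([_iv("chr1", 400, 1200, id="pk")])  # covers tiles 0-2
        pm = peak_matrix_from_tiles(tiles, peaks)
        assert pm.X[0, 0] == 2 + 3 + 5
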