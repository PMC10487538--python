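"""Normalization, feature selection, reduction, clustering and transfer."""

import numpy as np
import pytest
import scipy.sparse as sp

from screlink.io_intervals import CountsMatrix, GeneModel, GenomicInterval
from screlink.reduce_cluster import (
    ClusterAssignment,
    ReducedSpace,
    RnaReference,
    assign_cluster_celltypes,
    batch_center,
    cluster_graph,
    downsample_counts,
    filter_clusters,
    fit_rna_reference,
    gene_activity,
    iterative_lsi,
    label_transfer,
    log_normalize,
    marker_scores,
    pca,
    scale_and_regress,
    select_hvg,
    tfidf,
)


class TestLogNormalize:
    def test_closed_form_value(self):
        X = np.zeros((1, 100), dtype=int)
        X[0, 0] = 10
        X[0, 1] = 9990
        ln = log_normalize(sp.csr_matrix(X))
        assert ln[0, 0] == pytest.approx(np.log(11.0), abs=1e-12)

    def test_zero_count_stays_zero(self):
        ln = log_normalize(sp.csr_matrix(np.array([[0, 5]])))
        assert ln[0, 0] == 0.0

    def test_depth_invariance(self, rng):
        X = rng.poisson(3.0, size=(1, 50)) + 1
        a = log_normalize(sp.csr_matrix(X)).toarray()
        b = log_normalize(sp.csr_matrix(2 * X)).toarray()
        assert np.allclose(a, b)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            log_normalize(sp.csr_matrix(np.array([[0, 0], [1, 2]])))


class TestSelectHvg:
    def test_constant_genes_never_selected(self, rng):
        X = rng.poisson(5.0, size=(100, 50))
        X[:, 10] = 7          # identical in every cell
        idx = select_hvg(sp.csr_matrix(X), n_top=40)
        assert 10 not in idx

    def test_full_selection_is_identity(self, rng):
        X = rng.poisson(5.0, size=(50, 20)) + 1
        idx = select_hvg(sp.csr_matrix(X), n_top=20)
        assert list(idx) == list(range(20))

    def test_too_many_requested_rejected(self, rng):
        with pytest.raises(ValueError):
            select_hvg(sp.csr_matrix(rng.poisson(2.0, (10, 5))), n_top=6)

    def test_planted_bimodal_markers_rank_high(self, rng):
        # the mean-variance trend needs non-variable genes at comparable
        # means, otherwise the fit absorbs the markers' variance
        n = 300
        X = rng.poisson(3.0, size=(n, 300))
        X[:, 5:50] = rng.poisson(13.0, size=(n, 45))   # trend anchors
        X[: n // 2, :5] += rng.poisson(20.0, size=(n // 2, 5))
        idx = select_hvg(sp.csr_matrix(X), n_top=10)
        assert set(range(5)) <= set(idx)


class TestScaleAndRegress:
    def test_orthogonal_covariate_leaves_centered_gene(self, rng):
        x = rng.normal(size=(100, 1))
        cov = rng.normal(size=100)
        cov -= cov.mean()
        x_orth = x - np.outer(cov, (cov @ x) / (cov @ cov))
        out = scale_and_regress(x_orth, covariate=cov)
        centered = x_orth - x_orth.mean(axis=0)
        expected = centered / centered.std(axis=0, ddof=1)
        assert np.allclose(out, np.clip(expected, -10, 10), atol=1e-10)

    def test_gene_linear_in_covariate_becomes_zero(self, rng):
        cov = rng.normal(size=80)
        gene = (3.0 * cov + 1.0).reshape(-1, 1)
        out = scale_and_regress(gene, covariate=cov)
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_residuals_match_normal_equations_oracle(self, rng):
        X = rng.normal(size=(60, 7))
        cov = rng.normal(size=60)
        out = scale_and_regress(X, covariate=cov)
        A = np.column_stack([np.ones(60), cov - cov.mean()])
        beta = np.linalg.lstsq(A, X, rcond=None)[0]
        resid = X - A @ beta
        resid = resid / resid.std(axis=0, ddof=1)
        assert np.allclose(out, np.clip(resid, -10, 10), atol=1e-8)


class TestPca:
    def test_rank_one_data_single_component(self, rng):
        u = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 30))
        X = u @ v + rng.normal(scale=1e-4, size=(200, 30))
        space = pca(X, n_components=5)
        var = space.embedding.var(axis=0)
        assert var[0] / var.sum() > 0.99

    def test_components_orthogonal(self, rng):
        space = pca(rng.normal(size=(80, 20)), n_components=10)
        G = space.components @ space.components.T
        assert np.allclose(G, np.eye(10), atol=1e-8)

    def test_projection_centered(self, rng):
        space = pca(rng.normal(size=(80, 20)), n_components=10)
        assert np.allclose(space.embedding.mean(axis=0), 0.0, atol=1e-8)

    def test_dims_cap_enforced(self, rng):
        with pytest.raises(ValueError, match="<= 50"):
            ReducedSpace(np.zeros((10, 60)), "pca", np.zeros(60), np.arange(60))


class TestTfidfAndLsi:
    def test_identical_cells_equal_rows(self):
        X = sp.csr_matrix(np.tile([1, 0, 2, 1], (5, 1)))
        out = tfidf(X, binarize=False).toarray()
        assert np.allclose(out, out[0])

    def test_depth_only_variation_dim_dropped(self, rng):
        # cells differ only in depth: the dominant dimension correlates
        # with depth and must be excluded from retained_dims
        base = (rng.uniform(size=400) < 0.3).astype(float)
        cells = []
        for i in range(300):
            depth = 0.2 + 1.8 * (i / 300)
            cells.append(rng.poisson(base * 3 * depth))
        m = CountsMatrix(
            sp.csr_matrix(np.array(cells)),
            [f"c{i}" for i in range(300)],
            [f"chr1:{j * 500}-{(j + 1) * 500}" for j in range(400)],
        )
        with pytest.warns(UserWarning, match="using all tiles"):
            space = iterative_lsi(m, n_var=25_000, dims=10, seed=0)
        dropped = np.setdiff1d(np.arange(10), space.retained_dims)
        assert dropped.size >= 1
        assert np.all(np.abs(space.depth_correlation[dropped]) > 0.75)

    def test_lsi_recovers_cell_types(self, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        co = small_cohort
        truth = co.truth.atac_cells
        good = (~truth["planted_low_quality"] & ~truth["is_doublet"]).to_numpy()
        atac = co.atac.subset_cells(good)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            space = iterative_lsi(atac, dims=15, seed=0)
        from sklearn.cluster import KMeans

        labels = KMeans(4, random_state=0, n_init=10).fit_predict(space.retained)
        ari = adjusted_rand_score(truth.loc[good, "cell_type"], labels)
        assert ari >= 0.9


class TestClusterGraph:
    def test_two_separated_blobs_two_clusters(self, rng):
        emb = np.vstack([
            rng.normal(0, 0.3, size=(100, 5)),
            rng.normal(8, 0.3, size=(100, 5)),
        ])
        space = ReducedSpace(emb, "pca", np.zeros(5), np.arange(5))
        asg = cluster_graph(space, k_nn=15, resolution=0.8, seed=0)
        assert asg.n_clusters == 2
        assert len(set(asg.labels[:100])) == 1

    def test_tiny_resolution_single_cluster(self, rng):
        emb = rng.normal(size=(150, 4))
        space = ReducedSpace(emb, "pca", np.zeros(4), np.arange(4))
        asg = cluster_graph(space, resolution=1e-4, seed=0)
        assert asg.n_clusters == 1

    def test_stable_under_permutation(self, rng):
        emb = np.vstack([
            rng.normal(0, 0.3, size=(60, 4)), rng.normal(6, 0.3, size=(60, 4))
        ])
        perm = rng.permutation(120)
        space1 = ReducedSpace(emb, "pca", np.zeros(4), np.arange(4),
                              barcodes=[str(i) for i in range(120)])
        space2 = ReducedSpace(emb[perm], "pca", np.zeros(4), np.arange(4),
                              barcodes=[str(i) for i in perm])
        a = cluster_graph(space1, seed=0).as_series()
        b = cluster_graph(space2, seed=0).as_series()
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a[b.index.astype(str)], b) == 1.0


class TestBatchCenter:
    def test_pure_shift_removed_exactly(self, rng):
        emb = rng.normal(size=(100, 6))
        shifted = emb.copy()
        shifted[50:] += 3.5
        batches = np.array(["a"] * 50 + ["b"] * 50)
        space = ReducedSpace(shifted, "pca", np.zeros(6), np.arange(6))
        out = batch_center(space, batches).embedding
        assert np.allclose(out[:50] - out[50:].mean(axis=0) + out[:50].mean(axis=0),
                           out[:50])
        assert np.allclose(out[:50].mean(axis=0), out[50:].mean(axis=0))

    def test_single_batch_identity(self, rng):
        emb = rng.normal(size=(40, 3))
        space = ReducedSpace(emb, "pca", np.zeros(3), np.arange(3))
        out = batch_center(space, np.array(["x"] * 40)).embedding
        assert np.allclose(out, emb)


class TestGeneActivity:
    tiles = [f"chr1:{j * 500}-{(j + 1) * 500}" for j in range(60)]

    def _atac(self, rows):
        X = np.zeros((len(rows), 60), dtype=int)
        for i, row in enumerate(rows):
            for j, c in row.items():
                X[i, j] = c
        return CountsMatrix(sp.csr_matrix(X), [f"c{i}" for i in range(len(rows))],
                            self.tiles)

    def test_gene_without_nearby_tiles_scores_zero(self):
        g = [GeneModel("g", GenomicInterval("chr1", 25_000, 27_000, id="g"), "+")]
        m = self._atac([{0: 10}])
        act = gene_activity(m, g)
        assert act.X[0, 0] == 0.0

    def test_tile_inside_body_weight_one(self):
        g = [GeneModel("g", GenomicInterval("chr1", 5_000, 7_000, id="g"), "+")]
        m = self._atac([{11: 7}])     # tile [5500,6000) inside the body
        act = gene_activity(m, g)
        assert act.X[0, 0] == pytest.approx(7.0)

    def test_matches_per_gene_loop_oracle(self, rng):
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 25_000))
            genes.append(GeneModel(
                f"g{i}", GenomicInterval("chr1", s, s + 2_000, id=f"g{i}"),
                "+" if rng.uniform() < 0.5 else "-",
            ))
        counts = rng.poisson(1.0, size=(5, 60))
        m = self._atac([
            {j: int(c) for j, c in enumerate(row) if c} for row in counts
        ])
        act = gene_activity(m, genes, promoter_ext=2000, decay_bp=5000)
        for gi, g in enumerate(genes):
            expected = np.zeros(5)
            for j in range(60):
                t0, t1 = j * 500, (j + 1) * 500
                if g.strand == "+":
                    lo, hi = g.body.start - 2000, g.body.end
                else:
                    lo, hi = g.body.start, g.body.end + 2000
                if t1 <= lo or t0 >= hi:
                    continue
                if t1 > g.body.start and t0 < g.body.end:
                    w = 1.0
                else:
                    d = g.body.start - t1 if t1 <= g.body.start else t0 - g.body.end
                    w = np.exp(-max(d, 0) / 5000.0)
                expected += counts[:, j] * w
            got = act.X[:, gi].toarray().ravel()
            assert np.allclose(got, expected, atol=1e-9)


class TestDownsampleCounts:
    def test_target_depth_approached(self, rng):
        X = sp.csr_matrix(rng.poisson(5.0, size=(50, 100)))
        thin = downsample_counts(CountsMatrix(
            X, [f"c{i}" for i in range(50)], [f"g{j}" for j in range(100)]
        ), target_depth=100, seed=0)
        totals = np.asarray(thin.sum(axis=1)).ravel()
        assert abs(totals.mean() - 100) < 10
        assert (thin.toarray() <= X.toarray()).all()


class TestLabelTransfer:
    def _ref(self, rng):
        # two well-separated types in expression space
        n = 120
        counts = rng.poisson(2.0, size=(n, 60)) + 1
        counts[:60, :15] += rng.poisson(15.0, size=(60, 15))
        counts[60:, 15:30] += rng.poisson(15.0, size=(60, 15))
        m = CountsMatrix(sp.csr_matrix(counts), [f"r{i}" for i in range(n)],
                         [f"g{j}" for j in range(60)])
        labels = np.array(["A"] * 60 + ["B"] * 60)
        return fit_rna_reference(m, labels, n_hvg=60, n_components=10), m

    def test_identical_query_gets_label_with_score_one(self, rng):
        ref, m = self._ref(rng)
        query = CountsMatrix(m.X.copy(), [f"q{i}" for i in range(120)],
                             list(m.features))
        table, imputed = label_transfer(ref, query, k=15)
        assert (table["label"].to_numpy() == ref.labels).mean() > 0.97
        assert table["prediction_score"].median() == 1.0

    def test_score_at_half_is_excluded(self):
        table_cols = {"prediction_score": 0.5}
        # boundary semantics live in the exclusion rule: <= min_score
        import pandas as pd

        t = pd.DataFrame({"prediction_score": [0.5, 0.51]})
        excluded = t["prediction_score"] <= 0.5
        assert list(excluded) == [True, False]

    def test_transfer_accuracy_on_cohort(self, pipeline_result, default_cohort):
        res = pipeline_result
        truth = default_cohort.truth.cell_table
        af = res["atac_final"]
        acc = (res["labels_final"] == truth.loc[af.barcodes, "cell_type"]).mean()
        assert acc >= 0.9

    def test_constraint_without_reference_sample_rejected(self, rng):
        ref, m = self._ref(rng)
        query = CountsMatrix(m.X[:10], [f"q{i}" for i in range(10)],
                             list(m.features))
        import pandas as pd

        query.obs = pd.DataFrame({"sample": ["S9"] * 10}, index=query.barcodes)
        ref.samples = np.array(["S1"] * 120)
        with pytest.raises(ValueError, match="fewer reference|no reference"):
            label_transfer(ref, query, k=15, constrain_by_sample=True)


class TestClusterLabels:
    def test_pure_cluster_gets_its_type(self):
        asg = ClusterAssignment(np.array([0, 0, 1, 1]), list("abcd"), 0.8)
        out = assign_cluster_celltypes(asg, np.array(["T", "T", "B", "B"]))
        assert out.cluster_celltype == {0: "T", 1: "B"}

    def test_majority_wins_60_40(self):
        labels = np.array(["T"] * 6 + ["B"] * 4)
        asg = ClusterAssignment(np.zeros(10, dtype=int), [str(i) for i in range(10)], 0.8)
        out = assign_cluster_celltypes(asg, labels)
        assert out.cluster_celltype[0] == "T"

    def test_rna_cluster_purity_on_cohort(self, pipeline_result, default_cohort):
        res = pipeline_result
        truth = default_cohort.truth.cell_table
        clusters = res["rna"]["clusters"]
        cells = truth.loc[res["rna_kept"].barcodes, "cell_type"].to_numpy()
        for c in range(clusters.n_clusters):
            sub = cells[clusters.labels == c]
            purity = (sub == res["rna"]["clusters"].cluster_celltype[c]).mean()
            assert purity > 0.8

    def test_filter_clusters_boundary(self):
        asg = ClusterAssignment(np.array([0] * 4 + [1] * 4), list("abcdefgh"), 0.8)
        asg.cluster_celltype = {0: "T", 1: "B"}
        counts = np.array([4999.0] * 4 + [5000.0] * 4)
        kept, mask = filter_clusters(asg, counts, mean_min=5000.0)
        assert kept == [1]
        assert mask.sum() == 4

    def test_filter_clusters_drop_label(self):
        asg = ClusterAssignment(np.array([0, 0, 1, 1]), list("abcd"), 0.8)
        asg.cluster_celltype = {0: "unassigned", 1: "T"}
        kept, _ = filter_clusters(asg, np.full(4, 9000.0))
        assert kept == [1]
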