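"""Rank-sum DE, Benjamini-Hochberg, and hypergeometric enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from screlink.differential import (
    benjamini_hochberg,
    hypergeom_enrich,
    rank_sum_test,
    wilcoxon_de,
)
from screlink.reduce_cluster import log_normalize


def _naive_bh(p):
    p = np.asarray(p, float)
    m = p.size
    q = np.empty(m)
    order = np.argsort(p, kind="stable")
    for pos, i in enumerate(order):
        rank = pos + 1
        q[i] = min(
            min(p[j] * m / (list(order).index(j) + 1) for j in order[pos:]), 1.0
        )
    return q


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_matches_naive_oracle_on_uniform_ps(self, rng):
        p = rng.uniform(size=200)
        assert np.allclose(benjamini_hochberg(p), _naive_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=1000)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), q_sm, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_q_bounds_and_monotonicity(self, rng):
        p = rng.uniform(size=300)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _exhaustive_rank_sum_p(a, b):
    """Enumerate all assignments of pooled ranks to group A."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    e = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - e) >= abs(w_obs - e) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("n1,n2", [(6, 6), (5, 7), (4, 8)])
    def test_exact_p_matches_enumeration_oracle(self, rng, n1, n2):
        for _ in range(5):
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.uniform(-1, 1), size=n2)
            _, p = rank_sum_test(a, b, method="exact")
            assert p == pytest.approx(_exhaustive_rank_sum_p(a, b), abs=1e-10)

    def test_asymptotic_close_to_scipy(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(0.5, size=70)
        _, p = rank_sum_test(a, b, method="asymptotic")
        p_scipy = stats.ranksums(a, b).pvalue
        # ours uses a continuity correction; agreement is approximate
        assert p == pytest.approx(p_scipy, rel=0.15, abs=0.01)

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            rank_sum_test([1, 2, 2], [2, 3, 4], method="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestWilcoxonDe:
    def _matrix(self, rng, n_a=60, n_b=60, n_genes=40, effect_cols=(), fold=4.0):
        mu = np.full((n_a + n_b, n_genes), 2.0)
        for c in effect_cols:
            mu[:n_a, c] *= fold
        counts = rng.poisson(mu)
        return log_normalize(sp.csr_matrix(counts + (counts.sum(1, keepdims=True) == 0)))

    def test_identical_groups_no_gene_passes(self, rng):
        ln = self._matrix(rng)
        out = wilcoxon_de(ln, np.arange(60), np.arange(60, 120),
                          [f"g{j}" for j in range(40)],
                          min_pct=0.0, min_diff_pct=0.0)
        assert out.empty

    def test_planted_effect_detected(self, rng):
        ln = self._matrix(rng, effect_cols=(3,), fold=8.0)
        out = wilcoxon_de(ln, np.arange(60), np.arange(60, 120),
                          [f"g{j}" for j in range(40)],
                          min_pct=0.0, min_diff_pct=0.0)
        assert "g3" in set(out["gene_id"])
        assert (out.loc[out.gene_id == "g3", "log2fc"] > 0).all()

    def test_overlapping_groups_rejected(self, rng):
        ln = self._matrix(rng)
        with pytest.raises(ValueError, match="disjoint"):
            wilcoxon_de(ln, np.arange(10), np.arange(5, 15), ["g"] * 40)

    def test_downsampling_is_seeded(self, rng):
        ln = self._matrix(rng, n_a=700, n_b=700, effect_cols=(0,), fold=6.0)
        genes = [f"g{j}" for j in range(40)]
        a = wilcoxon_de(ln, np.arange(700), np.arange(700, 1400), genes,
                        min_pct=0.0, min_diff_pct=0.0, seed=5)
        b = wilcoxon_de(ln, np.arange(700), np.arange(700, 1400), genes,
                        min_pct=0.0, min_diff_pct=0.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_type_one_error_calibrated_on_null(self):
        # CLT-scale null: pooled fraction of p < 0.05 stays near 5%
        frac = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            counts = rng.poisson(3.0, size=(200, 150))
            ln = log_normalize(sp.csr_matrix(counts + (counts.sum(1, keepdims=True) == 0)))
            X = ln.toarray()
            for j in range(150):
                _, p = rank_sum_test(X[:100, j], X[100:, j], method="asymptotic")
                frac.append(p < 0.05)
        rate = np.mean(frac)
        assert 0.03 <= rate <= 0.07


class TestHypergeomEnrich:
    def test_exact_small_case(self):
        # N=10, K=5, n=3, overlap=3 -> C(5,3)/C(10,3) = 10/120
        universe = [f"u{i}" for i in range(10)]
        sets = {"S": universe[:5]}
        out = hypergeom_enrich(universe[:3], sets, universe, q_max=1.0)
        assert out["p"].iloc[0] == pytest.approx(10 / 120, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        sets = {"S": universe[5:]}
        out = hypergeom_enrich(universe[:3], sets, universe, q_max=1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_tail_sum_oracle(self, rng):
        from math import comb

        universe = [f"u{i}" for i in range(40)]
        for _ in range(20):
            k_set = int(rng.integers(3, 20))
            n_query = int(rng.integers(3, 20))
            members = list(rng.choice(universe, size=k_set, replace=False))
            query = list(rng.choice(universe, size=n_query, replace=False))
            out = hypergeom_enrich(query, {"S": members}, universe, q_max=1.0)
            overlap = len(set(query) & set(members))
            N = 40
            p_exact = sum(
                comb(k_set, x) * comb(N - k_set, n_query - x)
                for x in range(overlap, min(k_set, n_query) + 1)
            ) / comb(N, n_query)
            assert out["p"].iloc[0] == pytest.approx(p_exact, abs=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            hypergeom_enrich(["zz"], {"S": ["a"]}, ["a", "b"])

    def test_enrichment_on_cohort_gene_sets(self, pipeline_result):
        enr = pipeline_result["enrichment"]
        assert "SET_MALE_UP" in set(enr["set_id"])
        assert (enr["q"] <= 0.01).all()
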