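"""PWM parsing, exact-p scanning, TF ranking and motif enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from screlink.motif import (
    Pwm,
    motif_enrichment,
    rank_hits_by_tf_expression,
    read_fasta,
    read_meme,
    scan,
    score_distribution,
)

MINIMAL_MEME = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M1
letter-probability matrix: alength= 4 w= 3 nsites= 100 E= 0
0.85 0.05 0.05 0.05
0.05 0.85 0.05 0.05
0.05 0.05 0.85 0.05
"""


def _random_pwm(rng, w, motif_id="R", background=None):
    probs = rng.dirichlet(np.ones(4) * 2.0, size=w).T
    bg = background if background is not None else np.full(4, 0.25)
    return Pwm(motif_id, probs, bg)


class TestReadMeme:
    def test_minimal_file_parsed(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MINIMAL_MEME)
        pwms = read_meme(p)
        assert len(pwms) == 1
        assert pwms[0].motif_id == "M1" and pwms[0].width == 3
        # pseudocount applied: probabilities close to stated, columns sum 1
        assert np.allclose(pwms[0].probs.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(pwms[0].probs[0, 0], 0.85, atol=1e-3)
        assert pwms[0].consensus() == "ACG"

    def test_malformed_alphabet_rejected(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(MINIMAL_MEME.replace("ALPHABET= ACGT", "ALPHABET= 0123"))
        with pytest.raises(Exception):
            read_meme(p)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            Pwm("x", np.full((4, 2), 0.25), np.array([0.5, 0.5, 0.5, 0.5]))


class TestScan:
    def test_consensus_scores_maximum(self, rng):
        pwm = _random_pwm(rng, 6)
        hits = scan(pwm, {"s": pwm.consensus()}, both_strands=False)
        assert hits["score"].iloc[0] == pytest.approx(pwm.max_score(), abs=0.01)

    def test_uniform_pwm_scores_zero(self):
        pwm = Pwm("u", np.full((4, 4), 0.25), np.full(4, 0.25))
        hits = scan(pwm, {"s": "ACGTACGT"}, both_strands=False)
        assert np.allclose(hits["score"], 0.0, atol=1e-9)
        assert np.allclose(hits["p"], 1.0)

    def test_short_sequence_yields_no_windows(self, rng):
        pwm = _random_pwm(rng, 8)
        hits = scan(pwm, {"s": "ACGT"})
        assert hits.empty

    def test_windows_with_n_skipped(self, rng):
        pwm = _random_pwm(rng, 4)
        hits = scan(pwm, {"s": "ACGTNACGT"}, both_strands=False)
        # offsets 1-4 all touch the N
        assert set(hits["offset"]) == {0, 5}

    def test_distribution_sums_to_one(self, rng):
        for w in (3, 6, 10):
            pwm = _random_pwm(rng, w)
            _, dist = score_distribution(pwm)
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("w", [4, 6, 8])
    def test_dp_pvalues_match_exhaustive_enumeration(self, rng, w):
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = _random_pwm(rng, w, background=bg)
        from screlink.motif import _int_scores

        ints = _int_scores(pwm, 1e-3)
        offset, dist = score_distribution(pwm, 1e-3)
        tail = np.cumsum(dist[::-1])[::-1]
        # enumerate every possible window and its exact probability
        scores, probs = {}, {}
        for word in itertools.product(range(4), repeat=w):
            s = int(sum(ints[b, j] for j, b in enumerate(word)))
            pr = float(np.prod([bg[b] for b in word]))
            probs[s] = probs.get(s, 0.0) + pr
        achieved = sorted(probs)
        for s in achieved:
            p_enum = sum(pr for t, pr in probs.items() if t >= s)
            p_dp = tail[s - offset]
            assert p_dp == pytest.approx(p_enum, abs=1e-9)

    def test_reverse_complement_symmetry(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        pwm = _random_pwm(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        rc = seq.translate(comp)[::-1]
        fwd = scan(pwm, {"s": seq})
        rev = scan(pwm, {"s": rc})
        key = ["score", "p"]
        a = fwd.sort_values(key).reset_index(drop=True)[key].round(9)
        b = rev.sort_values(key).reset_index(drop=True)[key].round(9)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_sites_recovered_and_shuffled_clean(self, rng):
        pwm = Pwm("plant", np.where(np.eye(4)[:, [0, 1, 2, 3, 0, 1, 2, 3]] > 0,
                                    0.97, 0.01), np.full(4, 0.25))
        cons = pwm.consensus()
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            seqs, offsets = {}, {}
            for i in range(8):
                s = list(r.choice(list("ACGT"), size=200))
                off = int(r.integers(20, 160))
                s[off : off + len(cons)] = list(cons)
                seqs[f"s{i}"] = "".join(s)
                offsets[f"s{i}"] = off
            hits = scan(pwm, seqs)
            sig = hits[hits["q"] < 0.01]
            for sid, off in offsets.items():
                assert off in set(sig.loc[sig.sequence_id == sid, "offset"])
            shuffled = {
                sid: "".join(r.permutation(list(s))) for sid, s in seqs.items()
            }
            null_hits = scan(pwm, shuffled)
            # permutation may rarely recreate the consensus; exact-match
            # windows aside, no sub-maximal window reaches significance
            null_sig = null_hits[null_hits["q"] < 0.01]
            assert (null_sig["score"] >= pwm.max_score() - 1e-6).all()


class TestRanking:
    def _hits(self):
        return pd.DataFrame({
            "motif_id": ["m1", "m1", "m2", "m3"],
            "sequence_id": ["s"] * 4,
            "offset": [0, 5, 2, 3],
            "strand": ["+"] * 4,
            "score": [5.0, 4.0, 6.0, 3.0],
            "p": [1e-6] * 4,
            "q": [1e-4, 1e-4, 1e-4, 0.5],
        })

    def test_sorted_by_tf_expression(self):
        out = rank_hits_by_tf_expression(self._hits(), {"m1": 2.0, "m2": 10.0})
        assert list(out["motif_id"]) == ["m2", "m1"]

    def test_missing_tf_ranks_last_and_flagged(self):
        out = rank_hits_by_tf_expression(self._hits(), {"m1": 2.0})
        assert list(out["motif_id"]) == ["m1", "m2"]
        assert bool(out["tf_missing"].iloc[-1])

    def test_no_significant_hits_empty(self):
        hits = self._hits()
        hits["q"] = 0.5
        assert rank_hits_by_tf_expression(hits, {}).empty


class TestMotifEnrichment:
    def test_planted_target_enrichment_reported(self, rng):
        # width 8: the best achievable window p (0.25^8) clears the 1e-4
        # per-peak containment threshold; shorter motifs cannot
        pwm = Pwm("plant", np.where(np.eye(4)[:, [0, 3, 1, 2, 0, 2, 3, 1]] > 0,
                                    0.97, 0.01), np.full(4, 0.25))
        cons = pwm.consensus()
        target, background = {}, {}
        for i in range(12):
            s = list(rng.choice(list("ACGT"), size=120))
            s[30 : 30 + len(cons)] = list(cons)
            target[f"t{i}"] = "".join(s)
            background[f"b{i}"] = "".join(rng.choice(list("ACGT"), size=120))
        out = motif_enrichment(target, background, [pwm])
        assert list(out["motif_id"]) == ["plant"]
        assert out["log2fc"].iloc[0] > 1.0

    def test_identical_fractions_not_reported(self, rng):
        pwm = _random_pwm(rng, 6)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=80))
                for i in range(20)}
        target = {k: v for k, v in list(seqs.items())[:10]}
        background = {k: v for k, v in list(seqs.items())[10:]}
        out = motif_enrichment(target, background, [pwm])
        assert out.empty

    def test_p_matches_hypergeometric_oracle(self, rng):
        from scipy import stats as ss

        pwm = Pwm("plant", np.where(np.eye(4)[:, [0, 1, 2, 3, 1, 0, 2, 3]] > 0,
                                    0.97, 0.01), np.full(4, 0.25))
        cons = pwm.consensus()
        target, background = {}, {}
        for i in range(10):
            s = list(rng.choice(list("ACGT"), size=100))
            if i < 7:
                s[10 : 10 + len(cons)] = list(cons)
            target[f"t{i}"] = "".join(s)
        for i in range(10):
            s = list(rng.choice(list("ACGT"), size=100))
            if i < 2:
                s[10 : 10 + len(cons)] = list(cons)
            background[f"b{i}"] = "".join(s)
        out = motif_enrichment(target, background, [pwm], fdr_max=1.0,
                               log2fc_min=-10)
        row = out.attrs.get("all", out).iloc[0]
        k_t, k_b = row["n_target_with"], row["n_background_with"]
        p_oracle = ss.hypergeom.sf(k_t - 1, 20, k_t + k_b, 10)
        assert row["p"] == pytest.approx(p_oracle, abs=1e-12)


class TestFasta:
    def test_read_fasta(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nACGT\n>b\nttga\n")
        seqs = read_fasta(p)
        assert seqs == {"a": "ACGT", "b": "TTGA"}
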