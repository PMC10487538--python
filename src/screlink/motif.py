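"""PWM motif scanning with exact p-values, ranking and enrichment.

Motifs arrive as MEME (minimal) files and are scanned FIMO-style: every
window of every sequence (both strands) gets a log-odds score in bits
against the background, an exact p-value ``P(score >= s)`` under the
background model computed by dynamic programming on integer-discretized
per-position scores, and a BH q-value over all windows scanned for that
motif. Significant motifs can be ranked by the expression of their
transcription factor in malignant cells, and motif containment can be
compared between a target and a background peak set with a hypergeometric
test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy import stats

from .differential import benjamini_hochberg

__all__ = [
    "Pwm",
    "read_meme",
    "read_fasta",
    "scan",
    "scan_all",
    "rank_hits_by_tf_expression",
    "motif_enrichment",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Position probability matrix with background and pseudocount applied."""

    motif_id: str
    probs: np.ndarray                # 4 x w, columns sum to 1
    background: np.ndarray           # length 4, sums to 1
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probs must be 4 x w")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        # apply pseudocount and renormalize columns
        p = self.probs + self.pseudocount * self.background[:, None]
        self.probs = p / p.sum(axis=0, keepdims=True)
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("probability columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x w log2(p / background) score matrix (bits)."""
        return np.log2(self.probs / self.background[:, None])

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        rc = Pwm.__new__(Pwm)
        rc.motif_id = self.motif_id
        rc.probs = self.probs[::-1, ::-1].copy()
        rc.background = self.background[::-1].copy()
        rc.pseudocount = self.pseudocount
        return rc

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


def read_meme(path: str | os.PathLike, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse a MEME (minimal) motif file into Pwm objects.

    The letter-probability matrices and the stated background frequencies
    are used; the pseudocount is applied on load.
    """
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg = record.background
    background = np.array([bg[b] for b in _BASES], dtype=float)
    out = []
    for m in record:
        w = m.length
        probs = np.zeros((4, w))
        total = None
        for bi, b in enumerate(_BASES):
            col = np.asarray(m.counts[b], dtype=float)
            probs[bi] = col
        total = probs.sum(axis=0)
        probs = probs / total
        out.append(Pwm(m.name, probs, background, pseudocount=pseudocount))
    if not out:
        raise ValueError(f"no motifs parsed from {path}")
    return out


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Sequence id -> uppercase sequence."""
    seqs = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


# ---------------------------------------------------------------------------
# Exact score distribution and scanning
# ---------------------------------------------------------------------------

def _int_scores(pwm: Pwm, granularity: float) -> np.ndarray:
    """Per-position integer-discretized log-odds (units of ``granularity``
    bits)."""
    return np.round(pwm.log_odds() / granularity).astype(np.int64)


def score_distribution(pwm: Pwm, granularity: float = 1e-3):
    """Exact null distribution of the discretized window score under the
    background: returns (offset, probs) where probs[i] is the probability of
    integer score offset+i. Probabilities sum to 1 within 1e-9."""
    s = _int_scores(pwm, granularity)
    bg = pwm.background
    dist = None
    offset = 0
    for j in range(pwm.width):
        col = s[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        step = np.zeros(cmax - cmin + 1)
        for bi in range(4):
            step[col[bi] - cmin] += bg[bi]
        if dist is None:
            dist, offset = step, cmin
        else:
            dist = np.convolve(dist, step)
            offset += cmin
    return offset, dist


def _tail_pvalues(offset: int, dist: np.ndarray) -> np.ndarray:
    """tail[i] = P(score >= offset + i)."""
    return np.cumsum(dist[::-1])[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.size, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        code[arr == ord(b)] = i
    return code


def scan(
    pwm: Pwm,
    sequences: dict[str, str],
    both_strands: bool = True,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Score every window of every sequence against the PWM.

    Windows containing a non-ACGT base are skipped; sequences shorter than
    the motif yield no windows. Returns one row per scanned window with
    columns sequence_id, offset (forward-strand window start), strand,
    score (bits), p (exact tail probability), q (BH over all windows
    scanned for this motif).
    """
    w = pwm.width
    offset0, dist = score_distribution(pwm, granularity)
    tail = _tail_pvalues(offset0, dist)
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    rows = []
    for strand, mat in strands:
        ints = _int_scores(mat, granularity)
        for sid, seq in sequences.items():
            code = _encode(seq)
            n_win = code.size - w + 1
            if n_win <= 0:
                continue
            valid = np.ones(n_win, dtype=bool)
            bad = np.flatnonzero(code < 0)
            for b in bad:
                lo = max(0, b - w + 1)
                valid[lo : b + 1] = False
            win_idx = np.flatnonzero(valid)
            if win_idx.size == 0:
                continue
            scores = np.zeros(win_idx.size, dtype=np.int64)
            for j in range(w):
                scores += ints[code[win_idx + j], j]
            clip = np.clip(scores - offset0, 0, tail.size - 1)
            p = tail[clip]
            p = np.where(scores - offset0 >= tail.size, 0.0, p)
            p = np.where(scores < offset0, 1.0, p)
            p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
            for o, s, pv in zip(win_idx, scores, p):
                rows.append((sid, int(o), strand, float(s * granularity), float(pv)))
    df = pd.DataFrame(rows, columns=["sequence_id", "offset", "strand", "score", "p"])
    df["q"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    df.insert(0, "motif_id", pwm.motif_id)
    return df


def scan_all(
    pwms: list[Pwm],
    sequences: dict[str, str],
    both_strands: bool = True,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Concatenated :func:`scan` over motifs (q computed per motif)."""
    return pd.concat(
        [scan(m, sequences, both_strands, granularity) for m in pwms],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Ranking and enrichment
# ---------------------------------------------------------------------------

def rank_hits_by_tf_expression(
    hits: pd.DataFrame,
    tf_expression: dict[str, float],
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Motifs with at least one significant hit (q < ``q_max``), sorted by
    the summed malignant-cell expression of the corresponding transcription
    factor (descending). Motifs whose TF is absent from the expression table
    rank last and are flagged ``tf_missing``."""
    sig = hits[hits["q"] < q_max]
    if sig.empty:
        return pd.DataFrame(
            columns=["motif_id", "n_hits", "best_q", "tf_expression", "tf_missing"]
        )
    grp = sig.groupby("motif_id")
    df = pd.DataFrame(
        {
            "motif_id": list(grp.groups),
            "n_hits": grp.size().to_numpy(),
            "best_q": grp["q"].min().to_numpy(),
        }
    )
    df["tf_expression"] = df["motif_id"].map(tf_expression)
    df["tf_missing"] = df["tf_expression"].isna()
    df["tf_expression"] = df["tf_expression"].fillna(-np.inf)
    df = df.sort_values(
        ["tf_missing", "tf_expression", "motif_id"],
        ascending=[True, False, True], kind="stable",
    ).reset_index(drop=True)
    df["tf_expression"] = df["tf_expression"].replace(-np.inf, np.nan)
    return df


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[Pwm],
    fdr_max: float = 0.01,
    log2fc_min: float = 1.0,
    per_peak_p: float = 1e-4,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Hypergeometric containment test of each motif in target vs background
    peak sequences.

    A peak contains a motif iff at least one window scores ``p <
    per_peak_p``. The test draws the target peaks from the pooled
    target+background population; ``log2fc`` compares containment fractions
    with add-one smoothing. Rows passing ``q < fdr_max`` and ``log2fc >
    log2fc_min`` are returned (the full table is in ``attrs['all']``).
    """
    overlap = set(target_seqs) & set(background_seqs)
    if overlap:
        raise ValueError(f"peaks in both sets: {sorted(overlap)[:5]}")
    n_t, n_b = len(target_seqs), len(background_seqs)
    rows = []
    for pwm in pwms:
        hits_t = scan(pwm, target_seqs, granularity=granularity)
        hits_b = scan(pwm, background_seqs, granularity=granularity)
        k_t = hits_t.loc[hits_t["p"] < per_peak_p, "sequence_id"].nunique()
        k_b = hits_b.loc[hits_b["p"] < per_peak_p, "sequence_id"].nunique()
        K = k_t + k_b
        p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, K, n_t))
        log2fc = float(
            np.log2(((k_t + 1) / (n_t + 1)) / ((k_b + 1) / (n_b + 1)))
        )
        rows.append((pwm.motif_id, k_t, n_t, k_b, n_b, p, log2fc))
    df = pd.DataFrame(
        rows,
        columns=["motif_id", "n_target_with", "n_target", "n_background_with",
                 "n_background", "p", "log2fc"],
    )
    df["q"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    passing = df[(df["q"] < fdr_max) & (df["log2fc"] > log2fc_min)]
    passing = passing.sort_values(["q", "motif_id"], kind="stable").reset_index(drop=True)
    passing.attrs["all"] = df
    return passing
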