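"""Genomic interval types, interval algebra, and readers/writers.

Conventions
-----------
All coordinates are 0-based half-open ``[start, end)`` internally — the BED
convention. 1-based inclusive coordinates exist only at the printed-text
boundary (:func:`from_printed_coordinates` / :func:`to_printed_coordinates`).

Count matrices are cells x features in memory; on disk they follow the
CellRanger layout (MatrixMarket ``matrix.mtx`` with features as rows, plus
``barcodes.tsv`` and ``features.tsv``).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PeakSet",
    "CountsMatrix",
    "from_printed_coordinates",
    "to_printed_coordinates",
    "find_overlaps",
    "read_bed",
    "write_bed",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand is not None and self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def default_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-aware transcription start site."""

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: ``start`` for +, ``end - 1`` for -."""
        return self.body.start if self.strand == "+" else self.body.end - 1


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end, iv.id or "")


@dataclass
class PeakSet:
    """An ordered, uniquely-identified collection of genomic intervals.

    Intervals are canonically sorted by (chrom, start, end, id); intervals
    without an id receive ``chrom:start-end``.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    fixed_width: int | None = None

    def __post_init__(self):
        assigned = [
            iv if iv.id is not None else replace(iv, id=iv.default_id())
            for iv in self.intervals
        ]
        assigned.sort(key=_sort_key)
        ids = [iv.id for iv in assigned]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = dupes[dupes > 1].index.tolist()[:5]
            raise ValueError(f"duplicate peak ids: {dupes}")
        if self.fixed_width is not None:
            bad = [iv.id for iv in assigned if iv.width != self.fixed_width]
            if bad:
                raise ValueError(
                    f"fixed_width={self.fixed_width} violated by {bad[:5]}"
                )
        self.intervals = assigned

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def by_id(self) -> dict[str, GenomicInterval]:
        return {iv.id: iv for iv in self.intervals}

    def subset(self, keep_ids) -> "PeakSet":
        keep = set(keep_ids)
        return PeakSet(
            [iv for iv in self.intervals if iv.id in keep],
            fixed_width=self.fixed_width,
        )


# ---------------------------------------------------------------------------
# Printed-coordinate boundary
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^\s*([^:\s]+):([\d,]+)-([\d,]+)\s*$")


def from_printed_coordinates(text: str, one_based: bool = True) -> GenomicInterval:
    """Parse ``chrN:a-b`` (optionally comma-grouped) into an interval.

    With ``one_based=True`` the text is read as a 1-based inclusive range and
    converted to ``[a-1, b)``; with ``one_based=False`` it is taken verbatim
    as 0-based half-open ``[a, b)`` (the convention under which the 500-bp
    fixed-width enhancer coordinates printed in browser-track figures come
    out exactly one tile wide).
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse printed coordinates: {text!r}")
    chrom = m.group(1)
    a = int(m.group(2).replace(",", ""))
    b = int(m.group(3).replace(",", ""))
    if b < a:
        raise ValueError(f"end {b} < start {a} in {text!r}")
    if one_based:
        return GenomicInterval(chrom, a - 1, b)
    return GenomicInterval(chrom, a, b)


def to_printed_coordinates(iv: GenomicInterval, one_based: bool = True) -> str:
    """Inverse of :func:`from_printed_coordinates` (an involution)."""
    if one_based:
        return f"{iv.chrom}:{iv.start + 1:,}-{iv.end:,}"
    return f"{iv.chrom}:{iv.start:,}-{iv.end:,}"


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def find_overlaps(a: PeakSet, b: PeakSet, min_overlap: int = 1):
    """All pairs of intervals from ``a`` and ``b`` intersecting by at least
    ``min_overlap`` bp.

    Returns a list of ``(id_a, id_b, overlap_bp)`` tuples sorted by the
    canonical order of ``a`` then ``b``. Half-open adjacency ([0,500) vs
    [500,900)) is never an overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    payload: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        payload.setdefault(iv.chrom, [])
        trees.setdefault(iv.chrom, IntervalTree())
        trees[iv.chrom].addi(iv.start, iv.end, iv.id)
    out = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = []
        for node in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, node.end) - max(iv.start, node.begin)
            if ov >= min_overlap:
                hits.append((node.begin, node.end, node.data, ov))
        hits.sort()
        out.extend((iv.id, hid, ov) for _, _, hid, ov in hits)
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> PeakSet:
    """Read a BED3/BED6 file (0-based half-open, tab-separated) strictly.

    Column 4 becomes the interval id, column 5 the score, column 6 the
    strand, when present. Malformed lines raise with their line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            iv = GenomicInterval(
                cols[0],
                start,
                end,
                id=cols[3] if len(cols) > 3 and cols[3] != "." else None,
                score=float(cols[4]) if len(cols) > 4 and cols[4] != "." else None,
                strand=cols[5] if len(cols) > 5 else None,
            )
            intervals.append(iv)
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.id]
            if iv.score is not None or iv.strand is not None:
                cols.append("." if iv.score is None else repr(float(iv.score)))
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountsMatrix:
    """Sparse cells x features non-negative integer counts.

    ``feature_kind`` is one of ``gene``, ``tile``, ``peak``. ``obs`` carries
    per-cell metadata (sample, labels, QC metrics) indexed by barcode.
    """

    X: sp.csr_matrix
    barcodes: list[str]
    features: list[str]
    feature_kind: str = "gene"
    obs: pd.DataFrame | None = None

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            self.obs = self.obs.loc[self.barcodes].copy()

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_barcodes) -> "CountsMatrix":
        if isinstance(mask_or_barcodes, (list, pd.Index)) or (
            isinstance(mask_or_barcodes, np.ndarray)
            and mask_or_barcodes.dtype.kind in "UO"
        ):
            keep = set(mask_or_barcodes)
            idx = np.array([i for i, b in enumerate(self.barcodes) if b in keep])
        else:
            idx = np.flatnonzero(np.asarray(mask_or_barcodes))
        return CountsMatrix(
            self.X[idx],
            [self.barcodes[i] for i in idx],
            list(self.features),
            self.feature_kind,
            self.obs.iloc[idx],
        )

    def subset_features(self, idx) -> "CountsMatrix":
        idx = np.asarray(idx)
        return CountsMatrix(
            self.X[:, idx],
            list(self.barcodes),
            [self.features[i] for i in idx],
            self.feature_kind,
            self.obs,
        )


def read_counts_mtx(directory: str | os.PathLike, feature_kind: str | None = None) -> CountsMatrix:
    """Read a CellRanger-style triplet (matrix.mtx, barcodes.tsv, features.tsv).

    The on-disk matrix is features x barcodes; it is transposed to cells x
    features on ingest. Ingest is strict: dimension mismatches and negative
    or non-integer entries are errors, never silently repaired.
    """
    directory = os.fspath(directory)
    mat = scipy.io.mmread(os.path.join(directory, "matrix.mtx"))
    barcodes = pd.read_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str).tolist()
    feat = pd.read_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=None
    )
    features = feat[0].astype(str).tolist()
    kind = feature_kind
    if kind is None:
        kind = str(feat.iloc[0, feat.shape[1] - 1]) if feat.shape[1] > 1 else "gene"
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {mat.shape[0]} x {mat.shape[1]} but features.tsv has "
            f"{len(features)} rows and barcodes.tsv has {len(barcodes)} rows"
        )
    data = mat.data
    if data.size and data.min() < 0:
        raise ValueError("matrix.mtx contains negative entries")
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("matrix.mtx contains non-integer entries")
    X = sp.csr_matrix(mat.T.astype(np.int64))
    return CountsMatrix(X, barcodes, features, kind)


def write_counts_mtx(m: CountsMatrix, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"), sp.coo_matrix(m.X.T), field="integer"
    )
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(m.barcodes) + ("\n" if m.barcodes else ""))
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for f in m.features:
            fh.write(f"{f}\t{f}\t{m.feature_kind}\n")


# ---------------------------------------------------------------------------
# Gene models and gene sets
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read the 6-column gene TSV (gene_id, chrom, start, end, strand, tss)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene model TSV missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene_ids are not unique")
    genes = []
    for row in df.itertuples(index=False):
        gm = GeneModel(
            str(row.gene_id),
            GenomicInterval(str(row.chrom), int(row.start), int(row.end), id=str(row.gene_id)),
            str(row.strand),
        )
        if gm.tss != int(row.tss):
            raise ValueError(
                f"{row.gene_id}: tss column {row.tss} inconsistent with "
                f"strand-aware 5' end {gm.tss}"
            )
        genes.append(gm)
    return genes


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    rows = [
        (g.gene_id, g.body.chrom, g.body.start, g.body.end, g.strand, g.tss)
        for g in genes
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 columns")
            if cols[0] in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {cols[0]!r}")
            sets[cols[0]] = [g for g in cols[2:] if g]
    return sets
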