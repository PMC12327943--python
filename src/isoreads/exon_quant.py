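"""Exon-bin counting, first-exon usage, and normalized-expression summaries.

A read increments every bin that any of its aligned blocks overlaps by at
least one base, once per bin, mirroring flattened-exon differential usage
counting.  Raw counts carry a companion length-normalized table (counts per
kilobase of bin) for fold-change and relative-difference calculations.

First-exon usage is summarized per cell by the bounded statistic
``(Tr - F) / (Tr + F)``: the difference between reads assigned to the
truncated-isoform first exon and the full-length first exon, divided by
their sum.  Values above zero indicate a bias toward the truncated
promoter, below zero toward the full-length promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignments import ReadAlignment
from .gene_model import ExonBin, GeneModel

__all__ = [
    "BinCountTable",
    "count_bins",
    "first_exon_counts",
    "relative_difference",
    "normalize_expression",
    "group_fold_change",
]


@dataclass
class BinCountTable:
    """Raw and length-normalized bin x column (cell or group) counts."""

    counts: pd.DataFrame  # integer, bins x columns
    bin_lengths: pd.Series  # bases per bin

    @property
    def normalized(self) -> pd.DataFrame:
        """Counts per kilobase of bin."""
        return self.counts.div(self.bin_lengths / 1000.0, axis=0)

    def to_tsv(self, raw_path, normalized_path=None) -> None:
        self.counts.to_csv(raw_path, sep="\t")
        if normalized_path is not None:
            self.normalized.to_csv(normalized_path, sep="\t")


def count_bins(
    reads: Iterable[ReadAlignment],
    bins: Sequence[ExonBin],
    by: str = "cell_id",
) -> BinCountTable:
    """Count reads per exon bin, per cell (default) or per group.

    A read increments every bin any of its blocks overlaps by >=1 base,
    and never increments one bin twice.  Reads overlapping no bin (or on
    another chromosome) contribute nothing.
    """
    if by not in ("cell_id", "group"):
        raise ValueError("by must be 'cell_id' or 'group'")
    order = sorted(
        range(len(bins)), key=lambda i: (bins[i].interval.chrom, bins[i].interval.start)
    )
    bin_ids = [bins[i].bin_id for i in order]
    # per-chromosome sorted coordinate arrays for binary search
    index: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for row, i in enumerate(order):
        iv = bins[i].interval
        index.setdefault(iv.chrom, ([], [], []))  # type: ignore[arg-type]
        index[iv.chrom][0].append(iv.start)  # type: ignore[attr-defined]
        index[iv.chrom][1].append(iv.end)  # type: ignore[attr-defined]
        index[iv.chrom][2].append(row)
    index = {
        c: (np.array(s), np.array(e), rows) for c, (s, e, rows) in index.items()
    }
    tally: dict[tuple[int, str], int] = {}
    columns: list[str] = []
    seen_cols: set[str] = set()
    for read in reads:
        col = getattr(read, by)
        if col not in seen_cols:
            seen_cols.add(col)
            columns.append(col)
        if read.chrom not in index:
            continue
        starts, ends, rows = index[read.chrom]
        hit: set[int] = set()
        for bs, be in read.blocks:
            # bins with start < be and end > bs
            lo = int(np.searchsorted(ends, bs, side="right"))
            hi = int(np.searchsorted(starts, be, side="left"))
            hit.update(rows[j] for j in range(lo, hi))
        for row in hit:
            key = (row, col)
            tally[key] = tally.get(key, 0) + 1
    mat = pd.DataFrame(0, index=bin_ids, columns=columns, dtype=int)
    for (row, col), n in tally.items():
        mat.iat[row, mat.columns.get_loc(col)] = n
    lengths = pd.Series([bins[i].length for i in order], index=bin_ids)
    mat.index.name = "bin_id"
    return BinCountTable(counts=mat, bin_lengths=lengths)


def relative_difference(tr, f):
    """Bounded first-exon bias: (Tr - F) / (Tr + F), in [-1, 1].

    NaN is returned where Tr + F == 0 (the cell is excluded from group
    tests).  Accepts scalars or arrays; negative counts are an error.
    """
    tr_a = np.asarray(tr, dtype=float)
    f_a = np.asarray(f, dtype=float)
    if np.any(tr_a < 0) or np.any(f_a < 0):
        raise ValueError("first-exon counts must be non-negative")
    total = tr_a + f_a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (tr_a - f_a) / np.where(total > 0, total, 1), np.nan)
    if np.isscalar(tr) and np.isscalar(f):
        return float(out)
    return out


def first_exon_counts(
    reads: Iterable[ReadAlignment],
    gene: GeneModel,
    tr_label: str = "exon1T",
    f_label: str = "exon1",
) -> pd.DataFrame:
    """Per-cell counts of reads assigned to each alternative first exon.

    A read overlapping exactly one of the two first exons is assigned to
    it.  A read overlapping both (possible only for readthrough-type
    alignments) is assigned to the first exon containing its transcript-5'
    end — first-exon identity is a transcription-start statement — or to
    neither if its 5' end lies in neither exon.
    """
    by_label = gene.first_exons_by_label()
    for label in (tr_label, f_label):
        if label not in by_label:
            raise ValueError(f"gene {gene.gene_id} has no first exon labelled {label!r}")
    tr_ivs = [(iv.start, iv.end) for iv in by_label[tr_label]]
    f_ivs = [(iv.start, iv.end) for iv in by_label[f_label]]

    rows: dict[str, list] = {}
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        in_tr = any(read.overlaps(s, e) for s, e in tr_ivs)
        in_f = any(read.overlaps(s, e) for s, e in f_ivs)
        if in_tr and in_f:
            p5 = read.five_prime_pos
            in_tr = any(s <= p5 < e for s, e in tr_ivs)
            in_f = any(s <= p5 < e for s, e in f_ivs)
        if read.cell_id not in rows:
            rows[read.cell_id] = [read.group, 0, 0]
        if in_tr and not in_f:
            rows[read.cell_id][1] += 1
        elif in_f and not in_tr:
            rows[read.cell_id][2] += 1
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["group", "tr", "f"]
    )
    df.index.name = "cell_id"
    df["relative_difference"] = relative_difference(
        df["tr"].to_numpy(), df["f"].to_numpy()
    )
    return df


def normalize_expression(raw_count, cell_total):
    """Library-size normalized log expression: ln(1 + raw/total * 10,000).

    This is the standard per-cell normalization: raw feature counts divided
    by total cell counts, scaled by 10,000, natural-log transformed (with
    the usual +1 pseudocount so zero counts map to zero).
    """
    raw_a = np.asarray(raw_count, dtype=float)
    tot_a = np.asarray(cell_total, dtype=float)
    if np.any(raw_a < 0) or np.any(tot_a <= 0):
        raise ValueError("raw counts must be >=0 and cell totals > 0")
    out = np.log1p(raw_a / tot_a * 10_000.0)
    if np.isscalar(raw_count) and np.isscalar(cell_total):
        return float(out)
    return out


def group_fold_change(norm_a, norm_b) -> float:
    """Fold ratio of group means on the count scale.

    Normalized (log) expression values are de-logged (expm1) before
    averaging, so the ratio is of mean scaled counts, not of log means.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_b = float(np.mean(np.expm1(b)))
    mean_a = float(np.mean(np.expm1(a)))
    if mean_b == 0:
        warnings.warn("denominator group mean is zero; returning inf")
        return float("inf")
    return mean_a / mean_b
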