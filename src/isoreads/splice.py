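"""Splice-donor readthrough classification, junction counting, and
coverage-based alternative-splicing estimation.

A read crossing a splice-donor boundary is *spliced* if a block boundary
and gap begin exactly at the donor, *readthrough* if the alignment
continues contiguously at least ``min_readthrough`` bases into the intron,
and *excluded* otherwise (it ends before the donor, exactly at it, or
within ``min_readthrough`` bases past it — terminal bases are treated as
uncertain).  All logic is expressed in transcript orientation: on the
minus strand the donor boundary is the genomic start of the upstream exon
and "into the intron" means decreasing coordinates.

The internal-alternative-splicing proportion for an exon with an internal
donor is estimated from coverage extrema: (Cmax - Cmin) / Cmax, where Cmax
is the maximum depth between the exon's splice acceptor and the internal
donor and Cmin the minimum depth in the remainder of the exon after the
internal donor.  The statistic is scale-invariant, so raw depth is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import ReadAlignment
from .gene_model import GeneModel
from .stats import chi_square_yates

__all__ = [
    "DonorEvent",
    "CoverageProfile",
    "classify_at_donor",
    "readthrough_table",
    "compare_readthrough",
    "count_junction_reads",
    "coverage_profile",
    "altsplice_proportion",
]

SPLICED = "spliced"
READTHROUGH = "readthrough"
EXCLUDED = "excluded"


@dataclass(frozen=True, slots=True)
class DonorEvent:
    read_id: str
    donor: str
    verdict: str  # spliced | readthrough | excluded


def classify_at_donor(
    read: ReadAlignment,
    donor_pos: int,
    strand: str | None = None,
    min_readthrough: int = 10,
) -> str:
    """Verdict for one read at one splice-donor boundary.

    ``donor_pos`` is the half-open boundary coordinate of the exon/intron
    junction (exon end on '+', exon start on '-').  Every read receives
    exactly one verdict; reads not reaching the donor are excluded.
    """
    strand = strand or read.strand
    blocks = read.blocks
    if strand == "+":
        for i, (s, e) in enumerate(blocks):
            if e == donor_pos:
                return SPLICED if i < len(blocks) - 1 else EXCLUDED
            if s < donor_pos < e:
                return READTHROUGH if e - donor_pos >= min_readthrough else EXCLUDED
        return EXCLUDED
    for i, (s, e) in enumerate(blocks):
        if s == donor_pos:
            return SPLICED if i > 0 else EXCLUDED
        if s < donor_pos < e:
            return READTHROUGH if donor_pos - s >= min_readthrough else EXCLUDED
    return EXCLUDED


def donor_events(
    reads: Iterable[ReadAlignment],
    gene: GeneModel,
    donor_names: Sequence[str],
    min_readthrough: int = 10,
) -> list[DonorEvent]:
    """Per-read classification at each named donor of a gene."""
    donors = []
    for name in donor_names:
        site = gene.named_sites[name]
        if site.kind != "donor":
            raise ValueError(f"site {name!r} is not a donor")
        donors.append((name, site.pos))
    events = []
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        for name, pos in donors:
            verdict = classify_at_donor(read, pos, gene.strand, min_readthrough)
            events.append(DonorEvent(read.read_id, name, verdict))
    return events


def readthrough_table(
    reads: Sequence[ReadAlignment],
    gene: GeneModel,
    donor_names: Sequence[str],
    min_readthrough: int = 10,
) -> pd.DataFrame:
    """Per-group, per-donor spliced/readthrough counts and percentages.

    Rows with no informative (spliced or readthrough) reads are flagged by
    a NaN percentage.  Reads are pooled per group.
    """
    groups = []
    seen = set()
    for r in reads:
        if r.group not in seen:
            seen.add(r.group)
            groups.append(r.group)
    counts: dict[tuple[str, str], dict[str, int]] = {
        (g, d): {SPLICED: 0, READTHROUGH: 0, EXCLUDED: 0}
        for g in groups
        for d in donor_names
    }
    donors = [(name, gene.named_sites[name].pos) for name in donor_names]
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        for name, pos in donors:
            verdict = classify_at_donor(read, pos, gene.strand, min_readthrough)
            counts[(read.group, name)][verdict] += 1
    rows = []
    for (g, d), c in counts.items():
        informative = c[SPLICED] + c[READTHROUGH]
        pct = 100.0 * c[READTHROUGH] / informative if informative else float("nan")
        rows.append(
            {
                "group": g,
                "donor": d,
                "n_spliced": c[SPLICED],
                "n_readthrough": c[READTHROUGH],
                "n_excluded": c[EXCLUDED],
                "percent_readthrough": pct,
            }
        )
    return pd.DataFrame(rows)


def compare_readthrough(table: pd.DataFrame, donor: str, group_a: str, group_b: str):
    """Chi-square with Yates correction on the 2x2 spliced/readthrough table."""
    sub = table.set_index(["group", "donor"])
    a = sub.loc[(group_a, donor)]
    b = sub.loc[(group_b, donor)]
    t = np.array(
        [
            [a["n_readthrough"], a["n_spliced"]],
            [b["n_readthrough"], b["n_spliced"]],
        ]
    )
    return chi_square_yates(t)


def count_junction_reads(
    reads: Iterable[ReadAlignment], junction_key: tuple[str, int, int, str]
) -> int:
    """Reads with a block gap exactly matching the junction boundaries."""
    chrom, left, right, _strand = junction_key
    n = 0
    for read in reads:
        if read.chrom != chrom:
            continue
        if (left, right) in read.junctions:
            n += 1
    return n


@dataclass
class CoverageProfile:
    """Per-base read depth over [start, end) on one chromosome."""

    chrom: str
    start: int
    depth: np.ndarray  # int, length end - start

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def slice(self, start: int, end: int) -> np.ndarray:
        if start < self.start or end > self.end or start >= end:
            raise ValueError(f"[{start}, {end}) outside profile [{self.start}, {self.end})")
        return self.depth[start - self.start : end - self.start]

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            pos = self.start
            i = 0
            d = self.depth
            while i < len(d):
                j = i
                while j < len(d) and d[j] == d[i]:
                    j += 1
                fh.write(f"{self.chrom}\t{self.start + i}\t{self.start + j}\t{int(d[i])}\n")
                i = j


def coverage_profile(
    reads: Iterable[ReadAlignment], chrom: str, start: int, end: int
) -> CoverageProfile:
    """Per-base depth of aligned blocks over a genomic interval."""
    diff = np.zeros(end - start + 1, dtype=np.int64)
    for read in reads:
        if read.chrom != chrom:
            continue
        for s, e in read.blocks:
            a, b = max(s, start), min(e, end)
            if a < b:
                diff[a - start] += 1
                diff[b - start] -= 1
    return CoverageProfile(chrom, start, np.cumsum(diff[:-1]))


def altsplice_proportion(
    profile: CoverageProfile,
    acceptor_pos: int,
    internal_donor_pos: int,
    exon_end_pos: int,
    strand: str = "+",
) -> float:
    """Internal alternative-splicing proportion from coverage extrema.

    Boundary coordinates are genomic half-open positions; in transcript
    orientation the acceptor precedes the internal donor, which precedes
    the exon's own terminal boundary.  Returns (Cmax - Cmin)/Cmax with
    Cmax the maximum depth between acceptor and internal donor and Cmin
    the minimum depth in the rest of the exon; NaN if Cmax is zero.
    """
    if strand == "+":
        if not acceptor_pos < internal_donor_pos < exon_end_pos:
            raise ValueError(
                "plus strand requires acceptor < internal donor < exon end"
            )
        head = profile.slice(acceptor_pos, internal_donor_pos)
        tail = profile.slice(internal_donor_pos, exon_end_pos)
    else:
        if not exon_end_pos < internal_donor_pos < acceptor_pos:
            raise ValueError(
                "minus strand requires exon end < internal donor < acceptor"
            )
        head = profile.slice(internal_donor_pos, acceptor_pos)
        tail = profile.slice(exon_end_pos, internal_donor_pos)
    cmax = float(head.max())
    if cmax == 0:
        return float("nan")
    cmin = float(tail.min())
    return (cmax - cmin) / cmax
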