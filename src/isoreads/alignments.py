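"""Spliced read alignments and their SAM / tabular I/O.

A read is an ordered list of aligned genomic blocks; gaps between
consecutive blocks are splice junctions.  Each read carries a cell barcode
and a cell-group label so that all downstream tables can be computed per
cell or per group.  Two on-disk forms are supported: plain SAM (CIGAR built
from M/N runs, cell in the ``CB`` tag, group in ``XG``) and a simple TSV
dialect with blocks encoded as ``start-end,start-end,...`` (0-based
half-open), with ground-truth labels in a companion TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

__all__ = [
    "ReadTruth",
    "ReadAlignment",
    "write_tabular",
    "read_tabular",
    "write_truth",
    "read_truth",
    "write_sam",
    "read_sam",
    "read_alignments",
]


@dataclass(frozen=True, slots=True)
class ReadTruth:
    """Simulation ground truth attached to a read."""

    isoform: str
    terminated_at: int | None = None
    is_artifact: bool = False


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One spliced alignment: sorted, non-overlapping genomic blocks."""

    read_id: str
    cell_id: str
    group: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no aligned blocks")
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"read {self.read_id}: empty block [{s}, {e})")
        for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:]):
            if s1 - e0 < 1:
                raise ValueError(
                    f"read {self.read_id}: blocks overlap or touch (gap must be >=1)"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def five_prime_pos(self) -> int:
        """0-based position of the transcript-5' aligned base."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def three_prime_pos(self) -> int:
        """0-based position of the transcript-3' aligned base."""
        return self.blocks[-1][1] - 1 if self.strand == "+" else self.blocks[0][0]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Genomic gap boundary pairs (left, right) between blocks."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.blocks)


# ---------------------------------------------------------------------------
# Tabular dialect

_TAB_HEADER = ["read_id", "cell_id", "group", "chrom", "strand", "blocks"]


def _encode_blocks(blocks: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _decode_blocks(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_tabular(reads: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_HEADER) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.cell_id}\t{r.group}\t{r.chrom}\t{r.strand}\t"
                f"{_encode_blocks(r.blocks)}\n"
            )


def read_tabular(path, truth: dict[str, ReadTruth] | None = None) -> list[ReadAlignment]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TAB_HEADER:
            raise ValueError(f"unexpected tabular alignment header: {header}")
        for line in fh:
            rid, cid, grp, chrom, strand, blocks = line.rstrip("\n").split("\t")
            reads.append(
                ReadAlignment(
                    rid, cid, grp, chrom, strand, _decode_blocks(blocks),
                    truth=truth.get(rid) if truth else None,
                )
            )
    return reads


def write_truth(reads: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsource_isoform\tterminated_at\tis_artifact\n")
        for r in reads:
            t = r.truth
            if t is None:
                continue
            term = "" if t.terminated_at is None else str(t.terminated_at)
            fh.write(f"{r.read_id}\t{t.isoform}\t{term}\t{int(t.is_artifact)}\n")


def read_truth(path) -> dict[str, ReadTruth]:
    out: dict[str, ReadTruth] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, iso, term, art = line.rstrip("\n").split("\t")
            out[rid] = ReadTruth(
                isoform=iso,
                terminated_at=int(term) if term else None,
                is_artifact=bool(int(art)),
            )
    return out


# ---------------------------------------------------------------------------
# SAM


def _cigar_from_blocks(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def write_sam(
    reads: Sequence[ReadAlignment], path, chrom_lengths: dict[str, int]
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 60
            a.cigartuples = _cigar_from_blocks(r.blocks)
            a.set_tag("CB", r.cell_id)
            a.set_tag("XG", r.group)
            out.write(a)


def read_sam(path, truth: dict[str, ReadTruth] | None = None) -> list[ReadAlignment]:
    reads = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            blocks = tuple(a.get_blocks())
            reads.append(
                ReadAlignment(
                    read_id=a.query_name,
                    cell_id=a.get_tag("CB") if a.has_tag("CB") else "",
                    group=a.get_tag("XG") if a.has_tag("XG") else "",
                    chrom=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=blocks,
                    truth=truth.get(a.query_name) if truth else None,
                )
            )
    return reads


def read_alignments(path, truth_path=None) -> list[ReadAlignment]:
    """Load alignments by extension: .sam via pysam, .tsv via the dialect."""
    truth = read_truth(truth_path) if truth_path else None
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".sam":
        return read_sam(path, truth)
    if ext in (".tsv", ".txt"):
        return read_tabular(path, truth)
    raise ValueError(f"unrecognized alignment format: {path}")
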