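"""Gene and isoform structures, exon-bin flattening, and annotation I/O.

A gene is represented by its annotated transcript isoforms, each an ordered
chain of exons in transcript 5'->3' orientation.  The counting unit for exon
usage is the *exon bin*: a maximal genomic interval of exonic bases covered
by a constant set of isoforms, so that every bin lies entirely inside or
entirely outside each isoform's exon set.  Coordinates are 0-based half-open
throughout; GTF input (1-based inclusive) is converted at the boundary.

Minus-strand genes are handled by expressing all transcript-order logic
(first exon, donor side of a junction) in transcript orientation and
mirroring genomically: on the minus strand the splice donor of an exon is
its genomic *start* boundary and the acceptor its *end* boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import gffutils.feature

__all__ = [
    "GenomicInterval",
    "Isoform",
    "GeneModel",
    "ExonBin",
    "Site",
    "InvalidModelError",
    "GTFParseError",
    "flatten_isoforms",
    "name_junction",
    "load_gtf",
    "write_gtf",
    "write_bins_bed",
]


class InvalidModelError(ValueError):
    """A gene/isoform structure violates a model invariant."""


class GTFParseError(ValueError):
    """A GTF record could not be interpreted."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InvalidModelError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Isoform:
    """One annotated transcript: exons in transcript 5'->3' order.

    On the plus strand transcript order is increasing genomic coordinate;
    on the minus strand it is decreasing.
    """

    isoform_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise InvalidModelError(f"isoform {self.isoform_id} has no exons")
        strand = self.exons[0].strand
        chrom = self.exons[0].chrom
        for e in self.exons:
            if e.strand != strand or e.chrom != chrom:
                raise InvalidModelError(
                    f"isoform {self.isoform_id}: exons mix chrom/strand"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            ok = b.start >= a.end if strand == "+" else b.end <= a.start
            if not ok:
                raise InvalidModelError(
                    f"isoform {self.isoform_id}: exons overlap or are not in "
                    f"transcript order for strand {strand}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def first_exon(self) -> GenomicInterval:
        """The transcript-5' exon (alternative-promoter identity)."""
        return self.exons[0]

    @property
    def genomic_exons(self) -> tuple[GenomicInterval, ...]:
        """Exons sorted by genomic start, regardless of strand."""
        return tuple(sorted(self.exons, key=lambda e: e.start))

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Intron gaps as genomic boundary pairs (left, right), left < right."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return tuple(out)

    def donor_sites(self) -> tuple[int, ...]:
        """Genomic boundary coordinate of each splice donor, transcript order."""
        if self.strand == "+":
            return tuple(e.end for e in self.exons[:-1])
        return tuple(e.start for e in self.exons[:-1])

    def acceptor_sites(self) -> tuple[int, ...]:
        if self.strand == "+":
            return tuple(e.start for e in self.exons[1:])
        return tuple(e.end for e in self.exons[1:])


class Site(NamedTuple):
    pos: int
    kind: str  # donor | acceptor | termination


@dataclass
class GeneModel:
    """A gene: its isoforms plus named sites and first-exon role labels."""

    gene_id: str
    isoforms: dict[str, Isoform]
    named_sites: dict[str, Site] = field(default_factory=dict)
    first_exon_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise InvalidModelError(f"gene {self.gene_id} has no isoforms")
        chroms = {iso.chrom for iso in self.isoforms.values()}
        strands = {iso.strand for iso in self.isoforms.values()}
        if len(chroms) != 1 or len(strands) != 1:
            raise InvalidModelError(f"gene {self.gene_id}: isoforms mix chrom/strand")
        if not self.first_exon_labels:
            self.first_exon_labels = {
                iid: f"fe:{iso.first_exon.start}-{iso.first_exon.end}"
                for iid, iso in self.isoforms.items()
            }
        missing = set(self.isoforms) - set(self.first_exon_labels)
        if missing:
            raise InvalidModelError(
                f"gene {self.gene_id}: first_exon_labels missing for {sorted(missing)}"
            )
        for name, site in self.named_sites.items():
            self._check_site(name, site)

    # -- structure queries -------------------------------------------------

    @property
    def chrom(self) -> str:
        return next(iter(self.isoforms.values())).chrom

    @property
    def strand(self) -> str:
        return next(iter(self.isoforms.values())).strand

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for iso in self.isoforms.values() for e in iso.exons]
        ends = [e.end for iso in self.isoforms.values() for e in iso.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def donor_boundaries(self) -> set[int]:
        return {p for iso in self.isoforms.values() for p in iso.donor_sites()}

    def acceptor_boundaries(self) -> set[int]:
        return {p for iso in self.isoforms.values() for p in iso.acceptor_sites()}

    def exon_boundaries(self) -> set[int]:
        out: set[int] = set()
        for iso in self.isoforms.values():
            for e in iso.exons:
                out.update((e.start, e.end))
        return out

    def first_exons_by_label(self) -> dict[str, list[GenomicInterval]]:
        """Distinct first-exon intervals grouped by role label."""
        out: dict[str, list[GenomicInterval]] = {}
        for iid, iso in self.isoforms.items():
            label = self.first_exon_labels[iid]
            fe = iso.first_exon
            out.setdefault(label, [])
            if fe not in out[label]:
                out[label].append(fe)
        return out

    # -- named sites -------------------------------------------------------

    def _check_site(self, name: str, site: Site) -> None:
        if site.kind == "donor" and site.pos not in self.donor_boundaries():
            raise InvalidModelError(
                f"gene {self.gene_id}: donor {name}@{site.pos} is not an exon "
                f"boundary of any isoform"
            )
        if site.kind == "acceptor" and site.pos not in self.acceptor_boundaries():
            raise InvalidModelError(
                f"gene {self.gene_id}: acceptor {name}@{site.pos} is not an exon "
                f"boundary of any isoform"
            )
        if site.kind not in ("donor", "acceptor", "termination"):
            raise InvalidModelError(f"unknown site kind {site.kind!r}")

    def add_site(self, name: str, pos: int, kind: str) -> None:
        site = Site(pos, kind)
        self._check_site(name, site)
        self.named_sites[name] = site

    def site(self, name: str) -> Site:
        return self.named_sites[name]


@dataclass(frozen=True)
class ExonBin:
    """A maximal exonic interval with a constant covering-isoform set."""

    bin_id: str
    interval: GenomicInterval
    member_isoforms: frozenset[str]

    @property
    def length(self) -> int:
        return self.interval.length


def flatten_isoforms(gene: GeneModel) -> list[ExonBin]:
    """Partition a gene's exonic bases into disjoint counting bins.

    Boundaries are the union of all isoform exon boundaries; contiguous
    segments with identical covering-isoform sets are merged, giving the
    minimal partition in which every bin is entirely inside or entirely
    outside each isoform's exon set.  Bins are numbered in genomic order.
    """
    points = sorted(gene.exon_boundaries())
    segments: list[tuple[int, int, frozenset[str]]] = []
    for a, b in zip(points, points[1:]):
        members = frozenset(
            iid
            for iid, iso in gene.isoforms.items()
            if any(e.start <= a and e.end >= b for e in iso.exons)
        )
        if members:
            segments.append((a, b, members))
    merged: list[list] = []
    for a, b, members in segments:
        if merged and merged[-1][1] == a and merged[-1][2] == members:
            merged[-1][1] = b
        else:
            merged.append([a, b, members])
    return [
        ExonBin(
            bin_id=f"{gene.gene_id}:{i:03d}",
            interval=GenomicInterval(gene.chrom, a, b, gene.strand),
            member_isoforms=members,
        )
        for i, (a, b, members) in enumerate(merged, start=1)
    ]


def name_junction(
    gene: GeneModel, donor_pos: int, acceptor_pos: int
) -> tuple[str, int, int, str]:
    """Canonical strand-aware key for a splice junction.

    The key is (chrom, left, right, strand) with left < right the genomic
    boundary coordinates of the intron gap.  The donor is always the
    transcript-5' side: left on '+', right on '-'.
    """
    if gene.strand == "+":
        if acceptor_pos <= donor_pos:
            raise ValueError(
                f"plus strand requires acceptor > donor, got donor={donor_pos}, "
                f"acceptor={acceptor_pos}"
            )
        return (gene.chrom, donor_pos, acceptor_pos, "+")
    if acceptor_pos >= donor_pos:
        raise ValueError(
            f"minus strand requires acceptor < donor, got donor={donor_pos}, "
            f"acceptor={acceptor_pos}"
        )
    return (gene.chrom, acceptor_pos, donor_pos, "-")


# ---------------------------------------------------------------------------
# Annotation I/O


def load_gtf(path) -> list[GeneModel]:
    """Read exon features from an Ensembl-dialect GTF into GeneModels.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exons are grouped by (gene_id, transcript_id); transcript order follows
    the strand.  First-exon labels are auto-generated from the first exon's
    coordinates; assign biological roles (e.g. "FL" vs "Tr") afterwards via
    ``GeneModel.first_exon_labels``.
    """
    by_tx: dict[tuple[str, str], list] = {}
    strand_of: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # malformed record
                raise GTFParseError(f"line {lineno}: cannot parse GTF record: {exc}")
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise GTFParseError(f"line {lineno}: exon feature missing transcript_id")
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise GTFParseError(f"line {lineno}: exon feature missing gene_id")
            gid = attrs["gene_id"][0]
            tid = attrs["transcript_id"][0]
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            by_tx.setdefault((gid, tid), []).append(iv)
            strand_of[(gid, tid)] = feat.strand

    genes: dict[str, dict[str, Isoform]] = {}
    for (gid, tid), exons in by_tx.items():
        strand = strand_of[(gid, tid)]
        ordered = sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
        genes.setdefault(gid, {})[tid] = Isoform(tid, gid, tuple(ordered))
    return [GeneModel(gid, isoforms) for gid, isoforms in genes.items()]


def write_gtf(models: Iterable[GeneModel], path) -> None:
    """Write exon records (1-based inclusive coordinates, Ensembl attributes)."""
    with open(path, "w") as fh:
        for gene in models:
            for tid, iso in gene.isoforms.items():
                for e in iso.genomic_exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{e.chrom}\tisoreads\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )


def write_bins_bed(bins: Iterable[ExonBin], path) -> None:
    """Write exon bins as BED6 (score = number of member isoforms)."""
    with open(path, "w") as fh:
        for b in bins:
            iv = b.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.bin_id}\t"
                f"{len(b.member_isoforms)}\t{iv.strand}\n"
            )
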