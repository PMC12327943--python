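"""Synthetic genomes, gene models, and labelled spliced alignments.

The generator produces the two study situations every downstream stage
needs ground truth for:

* an alternative-promoter gene with two first exons ("exon1" for the
  full-length isoform, "exon1T" for the N-terminally truncated one)
  feeding shared downstream exons, plus an internally spliced variant of
  the shared second exon — on the minus strand, so transcript-order logic
  is exercised in mirror;
* a premature-transcription-termination (PTT) gene on the plus strand
  with named splice donors whose reads may read through contiguously into
  the intron and terminate at a configured intronic site, plus an
  independent 3' UTR transcription unit.

Reads are error-free and exactly block-aligned: the analyses consume
alignments, and the noise modes that matter to them (promoter choice,
donor readthrough, internal-priming artifacts) are modelled explicitly.
Each cell draws its reads' isoforms from its group's mixture; with a
configured probability a read's 3' end is relocated to a genomic A-rich
tract to emulate internal oligo(dT) priming.  A single seeded RNG stream
and fixed cell order make every dataset bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignments import ReadAlignment, ReadTruth
from .gene_model import GeneModel, GenomicInterval, Isoform

__all__ = [
    "PolyATract",
    "GeneSimSpec",
    "SimulationConfig",
    "SyntheticGenome",
    "ConfigError",
    "build_genome",
    "simulate_reads",
    "write_fasta",
    "two_first_exon_gene",
    "ptt_gene",
    "demo_config",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass(frozen=True)
class PolyATract:
    """A sequence tract inserted verbatim into the genome.

    For minus-strand genes the tract sequence should be T-rich on the
    forward strand so that it is A-rich in transcript orientation.
    """

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class GeneSimSpec:
    """Per-gene simulation design.

    mixture maps group -> {isoform_id: weight}; weights sum to 1 per group.
    readthrough maps donor-site name -> {group: probability}; a read whose
    exon chain crosses that donor continues into the intron with the given
    probability and terminates at ``termination[donor]`` (default
    donor + 200 bases in transcript direction).
    """

    model: GeneModel
    mixture: dict[str, dict[str, float]]
    readthrough: dict[str, dict[str, float]] = field(default_factory=dict)
    termination: dict[str, int] = field(default_factory=dict)
    artifact_rate: float = 0.0


@dataclass
class SimulationConfig:
    genes: list[GeneSimSpec]
    groups: dict[str, int]  # group label -> number of cells
    reads_per_cell: int = 100
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    tracts: list[PolyATract] = field(default_factory=list)
    fragment_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.genes:
            for group, weights in spec.mixture.items():
                total = sum(weights.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"mixture weights for gene {spec.model.gene_id} group "
                        f"{group} sum to {total}, not 1"
                    )
                if any(w < 0 or w > 1 for w in weights.values()):
                    raise ConfigError("mixture weights must lie in [0, 1]")
                unknown = set(weights) - set(spec.model.isoforms)
                if unknown:
                    raise ConfigError(f"mixture names unknown isoforms {unknown}")
            for donor, probs in spec.readthrough.items():
                if donor not in spec.model.named_sites:
                    raise ConfigError(f"readthrough donor {donor!r} not a named site")
                for p in probs.values():
                    if not 0.0 <= p <= 1.0:
                        raise ConfigError("readthrough probabilities must be in [0,1]")
            if not 0.0 <= spec.artifact_rate <= 1.0:
                raise ConfigError("artifact_rate must be in [0, 1]")


@dataclass
class SyntheticGenome:
    """Plain in-memory genome: chrom -> sequence string over {A,C,G,T}."""

    sequences: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for [start, end), clipped to the contig."""
        seq = self.sequences[chrom]
        return seq[max(start, 0) : min(end, len(seq))]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


def build_genome(config: SimulationConfig) -> SyntheticGenome:
    """Uniform-composition random genome with tracts inserted verbatim.

    Deterministic for a given seed.  A tract overlapping any exon boundary
    (splice site) of a configured gene model is a configuration error.
    """
    boundaries: dict[str, set[int]] = {}
    spans: dict[str, int] = dict(config.chrom_lengths)
    for spec in config.genes:
        g = spec.model
        boundaries.setdefault(g.chrom, set()).update(g.exon_boundaries())
        spans[g.chrom] = max(spans.get(g.chrom, 0), g.span.end + 1000)
    for t in config.tracts:
        for b in boundaries.get(t.chrom, ()):
            if t.start < b < t.end:
                raise ConfigError(
                    f"tract at {t.chrom}:{t.start} overlaps splice boundary {b}"
                )
        spans[t.chrom] = max(spans.get(t.chrom, 0), t.end + 100)

    rng = np.random.default_rng(config.seed)
    sequences = {}
    for chrom, length in spans.items():
        arr = _BASES[rng.integers(0, 4, size=length)]
        for t in config.tracts:
            if t.chrom == chrom:
                arr[t.start : t.end] = np.frombuffer(t.seq.encode(), dtype="S1")
        sequences[chrom] = arr.tobytes().decode()
    return SyntheticGenome(sequences)


def write_fasta(genome: SyntheticGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Read generation


def _transcript_blocks(iso: Isoform) -> list[list[int]]:
    """Mutable [start, end) blocks in transcript 5'->3' order."""
    return [[e.start, e.end] for e in iso.exons]


def _apply_readthrough(
    blocks: list[list[int]], iso: Isoform, spec: GeneSimSpec, group: str, rng
) -> int | None:
    """Extend the read past a donor into the intron; returns termination pos."""
    strand = iso.strand
    for i in range(len(blocks) - 1):
        boundary = blocks[i][1] if strand == "+" else blocks[i][0]
        for donor_name, probs in spec.readthrough.items():
            site = spec.model.named_sites[donor_name]
            if site.kind != "donor" or site.pos != boundary:
                continue
            p = probs.get(group, 0.0)
            if p > 0 and rng.random() < p:
                term = spec.termination.get(
                    donor_name, boundary + 200 if strand == "+" else boundary - 200
                )
                del blocks[i + 1 :]
                if strand == "+":
                    blocks[i][1] = term
                else:
                    blocks[i][0] = term
                return term
    return None


def _apply_artifact(
    blocks: list[list[int]], strand: str, tracts: list[PolyATract], chrom: str
) -> bool:
    """Relocate the 3' end to just transcript-upstream of an A-rich tract."""
    for t in tracts:
        if t.chrom != chrom:
            continue
        anchor = t.start if strand == "+" else t.end
        for i, (s, e) in enumerate(blocks):
            if s < anchor < e:
                if strand == "+":
                    blocks[i][1] = anchor
                    del blocks[i + 1 :]
                else:
                    blocks[i][0] = anchor
                    del blocks[i + 1 :]
                return True
    return False


def _fragment(blocks: list[list[int]], strand: str, frag_len: int, rng) -> list[list[int]]:
    """Uniform-start fragment of fixed length in transcript coordinates."""
    total = sum(e - s for s, e in blocks)
    if frag_len >= total:
        return blocks
    u = int(rng.integers(0, total - frag_len + 1))
    lo, hi = u, u + frag_len  # transcript coords
    out = []
    pos = 0
    for s, e in blocks:
        n = e - s
        a, b = max(lo - pos, 0), min(hi - pos, n)
        if a < b:
            if strand == "+":
                out.append([s + a, s + b])
            else:
                out.append([e - b, e - a])
        pos += n
    return out


def simulate_reads(
    config: SimulationConfig, genome: SyntheticGenome | None = None
) -> list[ReadAlignment]:
    """Generate labelled reads for every gene, cell, and group.

    Per cell, each read's isoform is drawn from the group's mixture; donor
    readthrough and internal-priming relocation are applied per read with
    their configured probabilities.  Reproducible for a fixed seed.
    """
    if genome is not None:
        for spec in config.genes:
            g = spec.model
            if g.span.end > genome.length(g.chrom):
                raise ConfigError(
                    f"gene {g.gene_id} extends past contig {g.chrom} end"
                )
    rng = np.random.default_rng(config.seed)
    reads: list[ReadAlignment] = []
    serial = 0
    for group, n_cells in config.groups.items():
        for ci in range(n_cells):
            cell_id = f"{group}_c{ci:04d}"
            for spec in config.genes:
                gene = spec.model
                weights = spec.mixture.get(group)
                if not weights:
                    continue
                iso_ids = sorted(weights)
                probs = np.array([weights[i] for i in iso_ids])
                choices = rng.choice(len(iso_ids), size=config.reads_per_cell, p=probs)
                for k in choices:
                    iso = gene.isoforms[iso_ids[k]]
                    blocks = _transcript_blocks(iso)
                    term = None
                    if spec.readthrough:
                        term = _apply_readthrough(blocks, iso, spec, group, rng)
                    is_art = False
                    if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
                        is_art = _apply_artifact(
                            blocks, iso.strand, config.tracts, gene.chrom
                        )
                    if config.fragment_length:
                        blocks = _fragment(
                            blocks, iso.strand, config.fragment_length, rng
                        )
                    serial += 1
                    reads.append(
                        ReadAlignment(
                            read_id=f"r{serial:07d}",
                            cell_id=cell_id,
                            group=group,
                            chrom=gene.chrom,
                            strand=iso.strand,
                            blocks=tuple(
                                sorted((s, e) for s, e in blocks)
                            ),
                            truth=ReadTruth(
                                isoform=iso.isoform_id,
                                terminated_at=term,
                                is_artifact=is_art,
                            ),
                        )
                    )
    return reads


# ---------------------------------------------------------------------------
# Template gene models


def two_first_exon_gene(gene_id: str = "ALTP1", chrom: str = "chrA") -> GeneModel:
    """Minus-strand gene with alternative first exons and an internally
    spliced variant of the shared second exon.

    Isoforms (transcript 5'->3'):
      FL      : exon1 [9000,9200) -> exon2 [6600,7000) -> exon3 [5000,5600)
      TR      : exon1T [8000,8150) -> exon2 -> exon3
      FL_DEX2 : exon1 -> exon2 head [6850,7000) (internal donor) -> exon3
    """
    strand = "-"
    e1 = GenomicInterval(chrom, 9000, 9200, strand)
    e1t = GenomicInterval(chrom, 8000, 8150, strand)
    e2 = GenomicInterval(chrom, 6600, 7000, strand)
    e2h = GenomicInterval(chrom, 6850, 7000, strand)
    e3 = GenomicInterval(chrom, 5000, 5600, strand)
    isoforms = {
        "FL": Isoform("FL", gene_id, (e1, e2, e3), label="FL"),
        "TR": Isoform("TR", gene_id, (e1t, e2, e3), label="Tr"),
        "FL_DEX2": Isoform("FL_DEX2", gene_id, (e1, e2h, e3), label="FL-dEx2"),
    }
    gene = GeneModel(
        gene_id,
        isoforms,
        first_exon_labels={"FL": "exon1", "TR": "exon1T", "FL_DEX2": "exon1"},
    )
    gene.add_site("donor_exon1", 9000, "donor")
    gene.add_site("donor_exon1T", 8000, "donor")
    gene.add_site("acceptor_exon2", 7000, "acceptor")
    gene.add_site("donor_exon2", 6600, "donor")
    gene.add_site("donor_exon2_internal", 6850, "donor")
    gene.add_site("acceptor_exon3", 5600, "acceptor")
    return gene


def ptt_gene(gene_id: str = "PTT1", chrom: str = "chrB") -> GeneModel:
    """Plus-strand gene with intronic premature-termination sites after the
    exon-4 and exon-6 donors and an independent 3' UTR transcription unit."""
    strand = "+"
    exons = [
        GenomicInterval(chrom, 1000 * i, 1000 * i + 200, strand) for i in range(1, 7)
    ]
    e7 = GenomicInterval(chrom, 7000, 7400, strand)
    utr = GenomicInterval(chrom, 7600, 8000, strand)
    isoforms = {
        "B_FULL": Isoform("B_FULL", gene_id, tuple(exons + [e7]), label="full"),
        "UTR3": Isoform("UTR3", gene_id, (utr,), label="3utr"),
    }
    gene = GeneModel(
        gene_id,
        isoforms,
        first_exon_labels={"B_FULL": "exon1", "UTR3": "utr"},
    )
    gene.add_site("donor_e4", 4200, "donor")
    gene.add_site("donor_e6", 6200, "donor")
    gene.add_site("ptt_i4", 4700, "termination")
    gene.add_site("ptt_i6", 6700, "termination")
    return gene


def demo_config(seed: int = 0) -> SimulationConfig:
    """Small end-to-end dataset covering every analysis stage.

    Mixtures follow the study regimes: rod-like cells favour the
    full-length first exon (~3:1) with rare internal exon-2 splicing,
    cone-like cells favour the truncated first exon (~0.67:1) with more
    frequent internal splicing; late-rod-like cells show elevated donor
    readthrough at the PTT gene.
    """
    ap = two_first_exon_gene()
    ptt = ptt_gene()
    ap_spec = GeneSimSpec(
        model=ap,
        mixture={
            "ER": {"FL": 0.699, "TR": 0.256, "FL_DEX2": 0.045},
            "LM": {"FL": 0.309, "TR": 0.599, "FL_DEX2": 0.092},
            "LR": {"FL": 0.64, "TR": 0.29, "FL_DEX2": 0.07},
        },
        artifact_rate=0.1,
    )
    ptt_spec = GeneSimSpec(
        model=ptt,
        mixture={
            "ER": {"B_FULL": 0.8, "UTR3": 0.2},
            "LM": {"B_FULL": 0.8, "UTR3": 0.2},
            "LR": {"B_FULL": 0.7, "UTR3": 0.3},
        },
        readthrough={
            "donor_e4": {"ER": 0.05, "LM": 0.05, "LR": 0.25},
            "donor_e6": {"ER": 0.05, "LM": 0.08, "LR": 0.40},
        },
        termination={"donor_e4": 4700, "donor_e6": 6700},
        artifact_rate=0.1,
    )
    tracts = [
        PolyATract("chrA", 5200, "T" * 20),
        PolyATract("chrB", 7100, "A" * 20),
    ]
    return SimulationConfig(
        genes=[ap_spec, ptt_spec],
        groups={"ER": 30, "LM": 30, "LR": 15},
        reads_per_cell=60,
        tracts=tracts,
        seed=seed,
    )


def expected_first_exon_reldiff(tr_weight: float, fl_weight: float) -> float:
    """Analytic per-cell relative difference for a Tr/FL mixture."""
    return (tr_weight - fl_weight) / (tr_weight + fl_weight)
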