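"""Independent brute-force oracles and random-instance generators.

Everything here is deliberately naive (per-base loops, regex scans,
exhaustive enumeration) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import re

import numpy as np

from isoreads.gene_model import GeneModel, GenomicInterval, Isoform


# ---------------------------------------------------------------------------
# Random gene models and reads


def random_gene(rng: np.random.Generator, gene_id="G", chrom="chr1",
                max_isoforms=5, max_exons=6, span=400) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(1, max_isoforms + 1))
    isoforms = {}
    for i in range(n_iso):
        n_ex = int(rng.integers(1, max_exons + 1))
        bounds = np.sort(rng.choice(np.arange(span), size=2 * n_ex, replace=False))
        exons = [
            GenomicInterval(chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]), strand)
            for j in range(n_ex)
        ]
        if strand == "-":
            exons = exons[::-1]
        iid = f"iso{i}"
        isoforms[iid] = Isoform(iid, gene_id, tuple(exons))
    return GeneModel(gene_id, isoforms)


def random_blocks(rng: np.random.Generator, span=400, max_blocks=4):
    n = int(rng.integers(1, max_blocks + 1))
    bounds = np.sort(rng.choice(np.arange(span), size=2 * n, replace=False))
    blocks = []
    for j in range(n):
        s, e = int(bounds[2 * j]), int(bounds[2 * j + 1])
        if blocks and s <= blocks[-1][1]:
            s = blocks[-1][1] + 1
            if s >= e:
                continue
        blocks.append((s, e))
    return tuple(blocks) if blocks else ((int(bounds[0]), int(bounds[0]) + 1),)


# ---------------------------------------------------------------------------
# Per-base flattening oracle


def perbase_partition(gene: GeneModel):
    """Maximal runs of exonic bases with constant covering-isoform sets."""
    members: dict[int, set[str]] = {}
    for iid, iso in gene.isoforms.items():
        for e in iso.exons:
            for p in range(e.start, e.end):
                members.setdefault(p, set()).add(iid)
    runs = []
    for p in sorted(members):
        m = frozenset(members[p])
        if runs and runs[-1][1] == p and runs[-1][2] == m:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1, m])
    return [(a, b, m) for a, b, m in runs]


# ---------------------------------------------------------------------------
# Per-base bin-count oracle


def perbase_bin_counts(reads, bins):
    """read x bin incidence computed base by base."""
    out = {}
    for read in reads:
        covered = set()
        for s, e in read.blocks:
            covered.update(range(s, e))
        for b in bins:
            iv = b.interval
            if iv.chrom != read.chrom:
                continue
            if any(iv.start <= p < iv.end for p in covered):
                out[(read.read_id, b.bin_id)] = 1
    return out


# ---------------------------------------------------------------------------
# Junction-count oracle


def gap_enumeration_count(reads, key):
    chrom, left, right, _ = key
    n = 0
    for read in reads:
        if read.chrom != chrom:
            continue
        for (s0, e0), (s1, e1) in zip(read.blocks, read.blocks[1:]):
            if e0 == left and s1 == right:
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# Artifact-rule scanning oracle (regex + explicit window loops)


def _windows(seq: str, w: int):
    if len(seq) <= w:
        return [seq]
    return [seq[i : i + w] for i in range(len(seq) - w + 1)]


def artifact_oracle(seq: str):
    seq = seq.upper()
    fired = set()
    if re.search("A{6,}", seq):
        fired.add("R1")
    if any(w.count("A") >= 8 for w in _windows(seq, 10)):
        fired.add("R2")
    if re.search("[AG]{6,}", seq):
        fired.add("R3")
    if any(w.count("A") + w.count("G") >= 8 for w in _windows(seq, 10)):
        fired.add("R4")
    if any(w.count("A") + w.count("T") >= 27 for w in _windows(seq, 30)):
        fired.add("R5")
    if any(w.count("A") >= 12 for w in _windows(seq, 18)):
        fired.add("R6")
    return bool(fired), fired


def random_seq(rng: np.random.Generator, n=30, a_rich=False) -> str:
    probs = [0.55, 0.15, 0.15, 0.15] if a_rich else [0.25] * 4
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))
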