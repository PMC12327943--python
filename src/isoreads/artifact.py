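"""Internal oligo(dT)-priming artifact filter for 3'-anchored long reads.

Reverse transcription primed inside a genomic A-rich tract (rather than at
the poly(A) tail) creates a spurious transcript 3' end.  Such reads are
recognized from the *genomic* sequence window immediately transcript-
downstream of the alignment's 3' end (reverse-complemented for minus-strand
reads) using six sequence-context rules; a read is an artifact if any rule
fires:

  R1  six or more consecutive adenines
  R2  more than seven (i.e. >=8) A in any 10-nt window
  R3  a run of only A/G of length >= 6
  R4  eight or more bases in {A, G} in any 10-nt window
  R5  high A/T content: >= 27 of 30 bases in {A, T}
  R6  twelve or more A in any 18-nt window

Windows slide by one base.  Non-ACGT symbols count toward no rule and
break runs.  The filter applies to oligo(dT)-primed (3'-anchored)
libraries; disable it for 5'-anchored data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignments import ReadAlignment

__all__ = [
    "ArtifactRuleSet",
    "TailContext",
    "DEFAULT_RULES",
    "tail_context",
    "evaluate_tail",
    "filter_reads",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ArtifactRuleSet:
    """Thresholds of the six tail-context rules (fixed by the method)."""

    r1_run_a: int = 6
    r2_a_count: int = 8
    r2_window: int = 10
    r3_run_ag: int = 6
    r4_ag_count: int = 8
    r4_window: int = 10
    r5_at_count: int = 27
    r5_window: int = 30
    r6_a_count: int = 12
    r6_window: int = 18

    @property
    def max_window(self) -> int:
        return max(self.r2_window, self.r4_window, self.r5_window, self.r6_window)


DEFAULT_RULES = ArtifactRuleSet()


@dataclass(frozen=True)
class TailContext:
    """Genomic window downstream of a read's 3' end, transcript orientation."""

    read_id: str
    window: str
    partial: bool = False  # fewer bases than requested were available


def tail_context(read: ReadAlignment, genome, window: int = 30) -> TailContext:
    """Extract the tail window from the reference genome (never the read).

    ``genome`` needs a ``fetch(chrom, start, end)`` method returning the
    clipped sequence (e.g. SyntheticGenome or pyfaidx-backed wrappers).
    """
    if read.strand == "+":
        anchor = read.blocks[-1][1]
        seq = genome.fetch(read.chrom, anchor, anchor + window)
    else:
        anchor = read.blocks[0][0]
        seq = _revcomp(genome.fetch(read.chrom, anchor - window, anchor))
    return TailContext(read.read_id, seq.upper(), partial=len(seq) < window)


def _max_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        if cur > best:
            best = cur
    return best


def _window_max_count(mask: np.ndarray, window: int) -> int:
    """Max count of True in any length-`window` window (whole seq if shorter)."""
    if len(mask) == 0:
        return 0
    if len(mask) <= window:
        return int(mask.sum())
    c = np.convolve(mask.astype(int), np.ones(window, dtype=int), mode="valid")
    return int(c.max())


def evaluate_tail(
    context: TailContext, rules: ArtifactRuleSet = DEFAULT_RULES
) -> tuple[bool, tuple[str, ...]]:
    """Apply all rules to one tail window; artifact iff any rule fires."""
    arr = np.frombuffer(context.window.encode(), dtype="S1")
    is_a = arr == b"A"
    is_g = arr == b"G"
    is_t = arr == b"T"
    fired = []
    if _max_run(is_a) >= rules.r1_run_a:
        fired.append("R1")
    if _window_max_count(is_a, rules.r2_window) >= rules.r2_a_count:
        fired.append("R2")
    if _max_run(is_a | is_g) >= rules.r3_run_ag:
        fired.append("R3")
    if _window_max_count(is_a | is_g, rules.r4_window) >= rules.r4_ag_count:
        fired.append("R4")
    if _window_max_count(is_a | is_t, rules.r5_window) >= rules.r5_at_count:
        fired.append("R5")
    if _window_max_count(is_a, rules.r6_window) >= rules.r6_a_count:
        fired.append("R6")
    return bool(fired), tuple(fired)


def filter_reads(
    reads: Sequence[ReadAlignment],
    genome,
    rules: ArtifactRuleSet = DEFAULT_RULES,
    window: int = 30,
    enabled: bool = True,
) -> tuple[list[ReadAlignment], list[tuple[ReadAlignment, tuple[str, ...]]], pd.DataFrame]:
    """Partition reads into kept vs internal-priming artifacts.

    Returns (kept, removed-with-fired-rules, per-rule removal counts).
    With ``enabled=False`` (5'-anchored libraries) all reads are kept.
    """
    kept: list[ReadAlignment] = []
    removed: list[tuple[ReadAlignment, tuple[str, ...]]] = []
    rule_counts = {f"R{i}": 0 for i in range(1, 7)}
    if not enabled:
        kept = list(reads)
    else:
        for read in reads:
            ctx = tail_context(read, genome, window)
            is_artifact, fired = evaluate_tail(ctx, rules)
            if is_artifact:
                removed.append((read, fired))
                for r in fired:
                    rule_counts[r] += 1
            else:
                kept.append(read)
    report = pd.DataFrame(
        {
            "rule": list(rule_counts),
            "reads_fired": list(rule_counts.values()),
        }
    )
    report.loc[len(report)] = ["removed_total", len(removed)]
    report.loc[len(report)] = ["kept_total", len(kept)]
    return kept, removed, report
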