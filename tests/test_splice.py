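"""Donor readthrough classification, junction counts, coverage splicing."""

import math

import numpy as np
import pytest

from isoreads.alignments import ReadAlignment
from isoreads.splice import (
    EXCLUDED,
    READTHROUGH,
    SPLICED,
    CoverageProfile,
    altsplice_proportion,
    classify_at_donor,
    compare_readthrough,
    count_junction_reads,
    coverage_profile,
    readthrough_table,
)
from isoreads.simulate import simulate_reads

from _oracles import gap_enumeration_count, random_blocks
from conftest import make_altsplice_config, make_ptt_readthrough_config


def _read(blocks, rid="r", cell="c", group="g", chrom="chr1", strand="+"):
    return ReadAlignment(rid, cell, group, chrom, strand, tuple(blocks))


class TestClassify:
    def test_gap_starting_at_donor_is_spliced(self):
        assert classify_at_donor(_read([(100, 200), (300, 350)]), 200) == SPLICED

    def test_contiguous_extension_is_readthrough(self):
        assert (
            classify_at_donor(_read([(100, 230)]), 200, min_readthrough=10)
            == READTHROUGH
        )

    def test_short_extension_is_excluded(self):
        assert (
            classify_at_donor(_read([(100, 205)]), 200, min_readthrough=10) == EXCLUDED
        )

    def test_alignment_ending_at_donor_is_excluded(self):
        assert classify_at_donor(_read([(100, 200)]), 200) == EXCLUDED

    def test_minus_strand_mirrors_all_verdicts(self):
        donor = 300  # exon [300,400) splices leftwards to [100,200)
        assert (
            classify_at_donor(_read([(100, 200), (300, 400)], strand="-"), donor)
            == SPLICED
        )
        assert (
            classify_at_donor(_read([(250, 400)], strand="-"), donor,
                              min_readthrough=10)
            == READTHROUGH
        )
        assert (
            classify_at_donor(_read([(295, 400)], strand="-"), donor,
                              min_readthrough=10)
            == EXCLUDED
        )
        assert classify_at_donor(_read([(300, 400)], strand="-"), donor) == EXCLUDED

    def test_every_read_gets_exactly_one_verdict(self, rng):
        for _ in range(300):
            read = _read(random_blocks(rng), strand="+" if rng.random() < 0.5 else "-")
            verdict = classify_at_donor(read, int(rng.integers(0, 400)))
            assert verdict in (SPLICED, READTHROUGH, EXCLUDED)


class TestReadthroughTable:
    def test_percent_is_readthrough_over_informative(self, ptt_model):
        reads = [
            _read([(4000, 4200), (5000, 5200)], rid=f"s{i}", chrom="chrB")
            for i in range(60)
        ] + [
            _read([(4000, 4700)], rid=f"t{i}", chrom="chrB") for i in range(40)
        ]
        table = readthrough_table(reads, ptt_model, ["donor_e4"])
        row = table.iloc[0]
        assert row["n_spliced"] == 60 and row["n_readthrough"] == 40
        assert row["percent_readthrough"] == pytest.approx(40.0)

    def test_simulated_probability_recovered(self, ptt_model):
        """25% readthrough recovered within 3 SE at 10,000 crossing reads."""
        cfg = make_ptt_readthrough_config(prob=0.25, n_reads=10_000, seed=47)
        table = readthrough_table(simulate_reads(cfg), ptt_model, ["donor_e4"])
        pct = table.iloc[0]["percent_readthrough"]
        se = 100 * math.sqrt(0.25 * 0.75 / 10_000)
        assert abs(pct - 25.0) < 3 * se

    def test_group_difference_power(self, rng):
        """probs 0.05 vs 0.25 at n=2,000: chi-square p<0.001 in >=95/100."""
        import pandas as pd

        hits = 0
        for _ in range(100):
            a_rt = rng.binomial(2000, 0.05)
            b_rt = rng.binomial(2000, 0.25)
            table = pd.DataFrame(
                [
                    {"group": "A", "donor": "donor_e4", "n_spliced": 2000 - a_rt,
                     "n_readthrough": a_rt},
                    {"group": "B", "donor": "donor_e4", "n_spliced": 2000 - b_rt,
                     "n_readthrough": b_rt},
                ]
            )
            res = compare_readthrough(table, "donor_e4", "A", "B")
            hits += res.p_value < 0.001
        assert hits >= 95


class TestJunctionCounts:
    def test_exact_gap_match_counted(self):
        read = _read([(100, 200), (300, 350)])
        assert count_junction_reads([read], ("chr1", 200, 300, "+")) == 1

    def test_near_miss_not_counted(self):
        read = _read([(100, 200), (310, 350)])
        assert count_junction_reads([read], ("chr1", 200, 300, "+")) == 0

    def test_matches_gap_enumeration_oracle(self, rng):
        reads = [_read(random_blocks(rng), rid=f"r{i}") for i in range(40)]
        for _ in range(30):
            donor = int(rng.integers(0, 400))
            acceptor = donor + int(rng.integers(1, 100))
            key = ("chr1", donor, acceptor, "+")
            assert count_junction_reads(reads, key) == gap_enumeration_count(
                reads, key
            )


class TestCoverage:
    def test_depth_matches_perbase_count(self, rng):
        reads = [_read(random_blocks(rng), rid=f"r{i}") for i in range(30)]
        prof = coverage_profile(reads, "chr1", 0, 400)
        for pos in rng.integers(0, 400, size=50):
            want = sum(
                any(s <= pos < e for s, e in r.blocks) for r in reads
            )
            assert prof.depth[pos] == want

    def test_bedgraph_runs_cover_profile(self, tmp_path, rng):
        reads = [_read(random_blocks(rng), rid=f"r{i}") for i in range(10)]
        prof = coverage_profile(reads, "chr1", 0, 400)
        p = tmp_path / "cov.bedgraph"
        prof.write_bedgraph(p)
        total = sum(
            (int(e) - int(s)) * int(d)
            for _, s, e, d in (l.split("\t") for l in p.read_text().splitlines())
        )
        assert total == int(prof.depth.sum())


class TestAltspliceProportion:
    def test_flat_profile_gives_zero(self):
        prof = CoverageProfile("chr1", 0, np.full(100, 50))
        assert altsplice_proportion(prof, 10, 50, 90) == 0.0

    def test_empty_tail_gives_one(self):
        depth = np.concatenate([np.full(50, 40), np.zeros(50)])
        prof = CoverageProfile("chr1", 0, depth)
        assert altsplice_proportion(prof, 10, 50, 90) == 1.0

    def test_zero_coverage_gives_nan(self):
        prof = CoverageProfile("chr1", 0, np.zeros(100))
        assert math.isnan(altsplice_proportion(prof, 10, 50, 90))

    @pytest.mark.parametrize("fraction", [0.06, 0.23, 0.5])
    def test_recovers_internal_splice_fraction(self, fraction, ap_gene):
        """Coverage extrema recover the configured fraction within 0.03."""
        cfg = make_altsplice_config(fraction, n_reads=4000, seed=53)
        reads = simulate_reads(cfg)
        prof = coverage_profile(reads, "chrA", 5000, 9200)
        got = altsplice_proportion(prof, 7000, 6850, 6600, strand="-")
        assert got == pytest.approx(fraction, abs=0.03)
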