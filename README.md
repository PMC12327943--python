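# isoreads

Read-level isoform analytics for full-length single-cell and long-read
transcriptomes.

Full-length scRNA-seq and long-read (e.g. RACE + nanopore) data make it
possible to ask *which transcript isoform* of a gene a cell expresses, not
just how much of the gene. Developmental biologists studying alternative
promoter choice (e.g. a full-length vs an N-terminally truncated
transcription-factor isoform distinguished by their first exons) or
premature transcription termination (transcription ending inside an
intron, truncating the protein) need a handful of read-level statistics
that standard expression pipelines do not produce. `isoreads` implements
them as a tested library plus a thin CLI:

- **Exon-bin quantification** — isoform exons are flattened into maximal
  disjoint bins with a constant covering-isoform set; a read counts once in
  every bin it overlaps; counts carry a per-kilobase-normalized companion.
- **Alternative first-exon usage** — per cell, reads assigned to the
  truncated-isoform first exon (Tr) vs the full-length first exon (F) are
  summarized by the bounded relative difference
  `(Tr − F) / (Tr + F)` ∈ [−1, 1]; >0 means truncated-promoter bias.
- **Splice-donor readthrough** — each read crossing a donor site is
  classified *spliced* (gap begins exactly at the donor), *readthrough*
  (contiguous alignment ≥ `min_readthrough` bases into the intron, default
  10), or *excluded*; per-group percentages quantify premature
  transcription termination.
- **Junction counting** — reads whose block gap exactly matches a named
  donor/acceptor pair, strand-aware.
- **Internal-priming artifact filter** — 3'-anchored reads whose genomic
  tail window (30 nt downstream of the 3' end, transcript orientation) is
  A-rich are removed via six rules (≥6 consecutive A; ≥8 A in 10 nt; A/G
  run ≥6; ≥8 A/G in 10 nt; ≥27/30 A/T; ≥12 A in 18 nt).
- **Coverage-based alternative splicing** — for an exon with an internal
  donor, the spliced proportion is `(Cmax − Cmin)/Cmax` from the coverage
  maximum before the internal donor and minimum after it.
- **Statistics** — Welch's t with bootstrap-null p-values
  `(1 + #{|t*| ≥ |t_obs|})/(1 + B)`, Kruskal–Wallis with Dunn post-hoc and
  Benjamini–Hochberg correction, and 2×2 chi-square with Yates continuity
  correction `Σ (max(|O−E|−½, 0))² / E`.
- **Synthetic data** — a seeded generator producing genomes (FASTA), gene
  models (GTF), and labelled spliced alignments (SAM or TSV) for an
  alternative-promoter gene and a premature-termination gene, with
  configurable mixture weights, readthrough probabilities, and
  internal-priming artifact rates, so every stage has ground truth.

Inputs are standard formats: GTF annotations, FASTA genomes, SAM or a
simple TSV alignment dialect with per-read cell and group labels.

## Worked example

Simulate a demo dataset (three cell groups: early-rod-like ER,
cone-like LM, late-rod-like LR) and run every stage:

```bash
isoreads simulate --outdir demo --seed 3
isoreads run-all --config demo/config.yaml --outdir out
```

`out/readthrough_summary.tsv` — percentage of donor-crossing reads that
read through into the intron (configured: 5% ER/LM vs 25% LR at the
exon-4 donor; 5/8/40% at the exon-6 donor):

```
group  donor     n_spliced  n_readthrough  n_excluded  percent_readthrough
ER     donor_e4  1344       81             375         5.68
LM     donor_e4  1358       58             384         4.10
LR     donor_e4  461        172            267         27.17
LR     donor_e6  270        191            439         41.43
```

`out/stats_results.tsv` — the first-exon relative difference differs
across groups (Kruskal–Wallis H = 55.8, p = 7.7e-13; the Dunn post-hoc in
`out/first_exon_dunn_pairwise.tsv` localizes it to ER vs LM,
BH-adjusted p = 8.6e-13), and readthrough is elevated in LR vs either
other group (Yates chi-square p = 2.7e-42 ER vs LR at the exon-4 donor)
while ER vs LM shows no excess (p = 0.061):

```
method            statistic  p_value      comparison
kruskal_dunn      55.80      7.66e-13     first_exon_relative_difference
chi_square_yates  3.52       6.08e-02     readthrough:donor_e4:ER_vs_LM
chi_square_yates  185.71     2.75e-42     readthrough:donor_e4:ER_vs_LR
```

`out/altsplice_proportions.tsv` — the internal exon-2 splicing proportion
from coverage extrema recovers the configured per-group fractions
(ER 0.045 → 0.054, LM 0.092 → 0.102 at this demo depth):

```
group  altsplice_proportion
ER     0.0539
LM     0.1022
LR     0.0522
```

Other outputs: `exon_bins.bed` (flattened bins, score = number of member
isoforms), `bin_counts_raw.tsv` / `bin_counts_per_kb.tsv`,
`first_exon_counts.tsv` (per cell: Tr, F, relative difference),
`junction_counts.tsv`, per-group coverage bedGraphs, and `manifest.json`
(version, seed, config hash, per-stage counts). Reruns with the same
config and seed are byte-identical.

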