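# Methods

## Coordinates and strand handling

All internal coordinates are 0-based half-open intervals; GTF input
(1-based inclusive) is converted at the parsing boundary and converted
back on write. All transcript-order logic — first-exon identity, the
donor side of a junction, "downstream into the intron", the tail window
of the artifact filter — is expressed in transcript orientation and
mirrored genomically on the minus strand: there, a donor is the genomic
*start* boundary of its exon, an acceptor the *end* boundary, and the
3' tail window lies at decreasing coordinates and is reverse-complemented.
Genes with alternative promoters and genes with premature termination
commonly sit on opposite strands in real genomes, so strand-generic logic
is mandatory; the two bundled gene templates are deliberately placed on
opposite strands so the mirrored paths are exercised by default.

## Exon bins

`flatten_isoforms` partitions a gene's exonic bases at the union of all
isoform exon boundaries and merges contiguous segments with identical
covering-isoform sets. The result is the minimal partition in which every
bin lies entirely inside or entirely outside each isoform's exon set —
the natural counting unit for differential exon usage. Bins are numbered
in genomic order (`gene:001`, ...); no minimum-length merging is applied.
`count_bins` increments a bin once per read if any aligned block overlaps
it by at least one base. Length normalization is counts per kilobase of
bin; the relative-difference and coverage-proportion statistics are
scale-invariant, so the normalization matters only for cross-bin fold
changes.

## First-exon usage

Reads are assigned to the truncated (Tr) or full-length (F) first exon by
overlap; a read overlapping both — possible only for readthrough-type
contiguous alignments — is assigned by the exon containing its
transcript-5' end, because first-exon identity is a statement about the
transcription start. Cells are summarized by
`(Tr − F)/(Tr + F)`; cells with `Tr + F = 0` get NaN and are dropped from
group tests. The statistic of a cell whose reads are i.i.d. draws with
truncated-isoform weight *p* concentrates at `2p − 1`, which is what the
recovery tests check (weights 0.75 → +0.5; 0.4 → −0.2).

## Donor readthrough

At a donor boundary *d*, a read is `spliced` when a block ends exactly at
*d* and a further block follows; `readthrough` when a block spans *d* and
continues at least `min_readthrough` bases past it; otherwise `excluded`
(ends before *d*, exactly at *d*, or within `min_readthrough` bases past
it). `min_readthrough` defaults to 10 bases: far below intron lengths but
enough to guard against boundary ambiguity and frayed terminal bases;
treating short extensions as excluded rather than readthrough is the
conservative choice. Percentages are pooled per group
(`100 · n_rt / (n_rt + n_spliced)`), and group pairs are compared with the
Yates-corrected chi-square.

## Coverage-based alternative splicing

For an exon with an internal donor, the spliced proportion is
`(Cmax − Cmin)/Cmax`, with `Cmax` the maximum per-base depth between the
exon's acceptor and the internal donor and `Cmin` the minimum depth in
the remainder of the same exon after the internal donor. This formalizes
a coverage-extrema readout (NaN when `Cmax = 0`). Depth is raw read
counts per group: the ratio is scale-invariant, so per-million
normalization is unnecessary. With full-length reads the estimator is an
exact binomial proportion of internally spliced molecules; the recovery
tests run it at ≥4,000× depth so the ±0.03 check sits several standard
errors from the configured fractions 0.06, 0.23, and 0.50.

## Internal-priming artifact filter

Oligo(dT)-primed libraries produce spurious 3' ends where the primer
anneals to a genomic A-rich tract. The filter inspects the *genomic*
30-nt window immediately transcript-downstream of each read's 3' end
(reverse-complemented on the minus strand; the window is genomic, never
read sequence, because the artifact signature is templated) and removes
the read if any rule fires:

| rule | definition |
|------|------------|
| R1 | ≥6 consecutive A |
| R2 | >7 (≥8) A in any 10-nt window |
| R3 | a run of only A/G, length ≥6 |
| R4 | ≥8 bases in {A,G} in any 10-nt window |
| R5 | ≥27 of 30 bases in {A,T} |
| R6 | ≥12 A in any 18-nt window |

Windows slide by one base; non-ACGT symbols count toward no rule and
break runs; at a contig end the available prefix is evaluated and the
context flagged partial. W = 30 is fixed by the largest rule span (R5).
Note that the purine rules R3/R4 fire on roughly half-purine sequence and
therefore remove an appreciable fraction of reads even on a uniform
random background; the false-positive property that is meaningfully
testable against a uniform genome concerns the adenine-specific rules
(R1/R2/R6), which fire on <2% of clean reads. The filter is intended for
3'-anchored (oligo-dT-primed) libraries only and is disabled by a config
switch for 5'-anchored data — the bundled demo configuration leaves it
off because the demo emulates 5'-anchored capture, and the filter is
exercised by its own subcommand and tests.

## Statistics

**Bootstrap Welch test.** The observed statistic is Welch's
`t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ)`. The null is built by shifting each
sample to the pooled mean and resampling *within* group with replacement —
this preserves each group's own variance, consistent with the
unequal-variance assumption (pooled resampling would impose equal
variances). The two-sided p-value uses add-one smoothing,
`(1 + #{|t*| ≥ |t_obs|})/(1 + B)`, so it is never exactly zero.
Degenerate resamples with zero variance in both groups count as extreme.
`B` defaults to 10,000; 1,000,000 is available by configuration for
full-replication analyses. Calibration over 1,000 null replicates at
n = 25 per group sits near the nominal 0.05.

**Kruskal–Wallis + Dunn + BH.** H uses mid-ranks with the standard tie
correction `1 − Σ(t³−t)/(N³−N)` (H defined as 0 when all observations are
identical). Dunn's pairwise z is
`(R̄ᵢ − R̄ⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)]` with
two-sided normal p-values, Benjamini–Hochberg-adjusted across all pairs.
BH is the step-up adjustment with monotone enforcement, order-preserving,
capped at 1.

**Yates chi-square.** `Σ (max(|O−E|−½, 0))²/E` on one degree of freedom;
the clamp prevents negative adjusted deviations on near-balanced tables.
Calibration under a balanced null at n = 1,000 per group is slightly
conservative (~0.045), as expected for the continuity correction.

## Synthetic data generator

The generator emulates the two study situations. The alternative-promoter
gene (minus strand) has first exons `exon1` (full-length isoform FL) and
`exon1T` (truncated isoform TR) splicing into shared exons 2–3, plus an
`FL_DEX2` isoform using an internal exon-2 donor. The
premature-termination gene (plus strand) has seven exons, named donors
after exons 4 and 6 with configured intronic termination sites, and an
independent single-exon 3' UTR transcription unit. Per group, each cell
draws `reads_per_cell` isoforms from the group's mixture; reads are
full-length, error-free, and exactly block-aligned — the analyses consume
alignments, and the noise modes that matter to them (promoter choice,
donor readthrough, internal-priming relocation) are modelled explicitly.
Readthrough at a named donor replaces the downstream splice with a
contiguous extension to the termination site; artifact relocation
truncates the read at a configured genomic A-tract (a T-tract on the
forward strand for minus-strand genes) and labels it in the truth record.
An optional fragmenting mode (uniform fragment starts, fixed length)
supports coverage-profile tests. A single seeded RNG stream with fixed
cell order makes datasets bit-reproducible.

What the generator does *not* emulate: sequencing errors, soft clips,
UMI/duplicate structure, variable capture efficiency along the
transcript, or expression variation beyond the two template genes.
Passing recovery tests therefore demonstrates correctness of the
estimators under their stated assumptions, not robustness to alignment
noise in real libraries.

The demo mixtures place the rod-like group near a 2.9:1 full-length:
truncated ratio with ~5% internal exon-2 splicing and the cone-like group
near 0.67:1 with ~23% internal splicing among full-length-promoter reads;
the late-rod group carries elevated readthrough (25%/40%) at the two
named donors. Sizes used in tests and the acceptance script — 200 cells ×
500 reads/cell for first-exon recovery, 10,000 crossing reads for
readthrough, 4,000 reads (≥4,000× exon depth) for the coverage
proportion, 1,000 replicates × 10,000 bootstrap resamples for
calibration — were chosen so every check sits several standard errors
inside its tolerance.

## Pipeline configuration

`run-all` (or `run_pipeline`) reads a YAML file:

```yaml
seed: 0
paths: {gtf: models.gtf, fasta: genome.fa, alignments: reads.tsv, truth: truth.tsv}
sites:            # named donors/acceptors added to loaded models
  - {gene: PTT1, name: donor_e4, pos: 4200, kind: donor}
first_exon_roles: # isoform -> first-exon label overrides
  ALTP1: {FL: exon1, TR: exon1T, FL_DEX2: exon1}
first_exon: {gene: ALTP1, tr_label: exon1T, f_label: exon1}
readthrough: {gene: PTT1, donors: [donor_e4, donor_e6], min_readthrough: 10}
junctions:
  - {gene: ALTP1, donor: 8000, acceptor: 7000, name: tr_junction}
altsplice: {gene: ALTP1, acceptor: 7000, internal_donor: 6850, exon_end: 6600}
artifact: {enabled: false, window: 30}
stats: {n_boot: 10000, alpha: 0.05}
```

Stages run in a fixed order (load → flatten → filter → counts →
readthrough/junctions → coverage proportion → statistics); any stage
failure aborts with the stage name; the manifest records version, seed,
config hash, and per-stage counts, and reruns are byte-identical.

## Known limitations

- Isoform role labels (FL vs Tr) are user-supplied metadata, not inferred
  from structure.
- Readthrough percentages are pooled per group; a per-cell variant would
  need a dispersion model the pooled chi-square does not provide.
- The coverage-extrema splicing proportion assumes near-uniform coverage
  across the exon (true for full-length reads; biased 3' coverage in real
  droplet data would distort it).
- The artifact filter's purine rules are aggressive by construction; on
  purine-rich clean transcripts they will remove genuine reads.
- Junction counting requires exact gap matches; it does not tolerate
  small alignment wobble around splice sites.
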