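# Methods

## Overview

`irtools` quantifies intron retention (IR) from spliced RNA-seq alignments
and relates it to junction-proximal epigenomic signal. The pipeline has five
analytical stages: (1) a synthetic-read mappability screen that removes
regions where intronic coverage cannot be measured reliably; (2) per-intron
quantification of splicing and intronic abundance, summarized as an IR
ratio; (3) two-sample differential IR testing with an exact test for digital
counts; (4) sliding-window metaprofiles of CpG methylation (beta values) and
ChIP fold enrichment around splice junctions and intron midpoints; and
(5) feature-level comparisons of retained vs non-retained introns. A
simulator generates fully self-contained datasets with known ground truth
so every stage is testable end to end.

## Intron catalogue

Introns are the distinct genomic gaps between consecutive exons of any
transcript of a gene, deduplicated by span within the gene. Introns sharing
one boundary but not the other (alternative donor/acceptor use) remain
separate records; identical gaps in two overlapping genes also remain
separate, since retention is reported per gene. All internal coordinates
are 0-based half-open; GTF input is converted at the parser boundary.

Two kinds of exclusion trim an intron's span to its *measurable* region,
both applied regardless of strand:

- **Foreign features** — exons of any other gene (miRNAs, snoRNAs, or an
  overlapping coding gene) intersecting the intron. Transcription from such
  features confounds the intronic depth signal whichever strand it is on.
- **Poor mappability** — from the synthetic-read screen below.

## Mappability screen

Synthetic reads of 70 nt are taken from the reference every 10 bp; every
second read is reverse-complemented, and one deterministic substitution
(A→C, C→G, G→T, T→A, N→A) is planted at 0-based position 34 (configurable)
before the orientation flip. Each read is re-aligned; a read counts toward
every base of its origin interval iff it maps *uniquely* back to that
origin — uniqueness meaning exactly one best-scoring location genome-wide
within a one-mismatch allowance, so a second location at equal or better
score disqualifies it. An interior base can be overlapped by at most
⌈70/10⌉ = 7 reads; any base with fewer than 5 uniquely-mapping overlapping
reads is poorly mappable, and maximal runs of failing bases form the mask.

The threshold is absolute, so chromosome ends — where fewer than 5
overlapping reads are geometrically possible — are always masked. The
built-in aligner is an exhaustive both-strand scan suitable for toy
genomes (vectorized over all windows; oracle-checked against a pure-Python
re-implementation in the tests); for real genomes the reads can be exported
as FASTA and an external aligner's SAM consumed instead, with uniqueness
taken from the NH tag.

## IR quantification

For each intron and sample:

- **Splice abundance** counts fragments whose alignment gap (cigar N) spans
  the intron. Exact spanners have both gap edges on the intron boundaries;
  one-sided counts anchor only the donor (5′) or only the acceptor (3′)
  edge, with the other end landing elsewhere (alternative splicing across
  the intron). Exact spanners are included in both one-sided tallies and
  the larger tally is used. The exact count is reported separately so the
  alternative convention (adding exact to the one-sided max) is recoverable.
- **Intronic abundance** is a trimmed mean of per-base fragment depth over
  the measurable spans only: masked positions are removed from the depth
  vector, not zero-filled. After sorting, ⌊0.30·n⌋ values are dropped from
  each end (for n < 4 nothing is dropped) and the remainder averaged. An
  intron with no measurable bases is *not assessable* — distinct from an
  IR ratio of zero.
- **IR ratio** = intronic / (intronic + splice), in [0, 1]; 0/0 is not
  assessable. An intron is called *retained* when the ratio is ≥ 0.10
  (inclusive).

Fragment-level counting is used throughout: with paired-end input the two
mates are merged into one fragment before counting, so a pair contributes
once to splice counts and once to depth.

The IR ratio compares two "fragments crossing a point" rates (intronic
depth per base vs junction-crossing count), so it is a consistent estimator
of the molar fraction of intron-retaining transcripts under standard
length-weighted library sampling; residual bias from the retained isoform
being longer than the spliced one is of order (1−r)·ΔL/L and small when
the intron is short relative to the transcript.

## Differential IR

The change in an intron's counts between two samples is evaluated with an
exact Bayesian test for digital counts. Given count x under total N1, the
posterior predictive for the second sample's count is

    p(y | x) = (N2/N1)^y · (x+y)! / (x!·y!·(1+N2/N1)^(x+y+1)),

i.e. Y|x is negative binomial with x+1 successes and success probability
N1/(N1+N2). Tails are evaluated in log space (gammaln + logsumexp); the
infinite upper tail is the complement of the finite lower sum, so counts up
to 10⁶ pose no overflow risk. The two-sided p-value doubles the smaller of
the two inclusive upper tails taken in each direction with totals swapped —
P(Y ≥ y | x; N1,N2) and P(X ≥ x | y; N2,N1) — which makes the construction
exchangeable between samples; doubling a single conditional's
inclusive lower/upper tails would not be.

By default x and y are the intronic abundances rounded half-up, with
per-intron totals N = intronic + splice, so the test asks whether the
intron's share of its local fragment pool shifted. The contrast is a thin
strategy layer; library-size totals can be swapped in. No multiple-testing
correction is applied by default (Benjamini–Hochberg is available behind a
flag).

An intron is called differential when all three cutoffs hold, with the
strictness as stated: p < 0.05; splice abundance strictly above 10 in both
samples; IR ratio strictly above 0.1 in at least one sample. Direction is
the sign of the IR-ratio change, and the fold change uses a 0.01
pseudocount on both ratios. Bias between increased and decreased calls is
assessed with an exact two-sided binomial test (doubled smaller tail) under
p₀ = 0.5.

## Junction metaprofiles

Beta values (methylated / total reads per CpG, kept only when coverage
exceeds five reads, i.e. ≥ 6) or ChIP fold-enrichment intervals are pooled
across all introns of a stratum into 20 contiguous 10-bp windows covering
±100 bp of an anchor: 5′ junction, 3′ junction, or intron midpoint
(start + ⌊width/2⌋). Profiles are transcription-oriented: on the minus
strand the offset axis flips (rel = anchor − 1 − pos), so negative offsets
of a 5′-junction profile are always exonic. Window mean = Σ values / number
of contributing sites, pooled across introns (not per-intron averaged);
empty windows are recorded as missing. Midpoint windows are clipped to the
intron so junction-adjacent signal is not double-counted in short introns.
Interval-valued ChIP records contribute their fold enrichment once to every
window they overlap.

The retained vs non-retained contrast is a classical paired t-test across
the ≤ 20 matched window means (df = pairs − 1), excluding windows missing
in either stratum pairwise; fewer than 3 complete pairs is an error, and
exactly constant non-zero differences are reported as degenerate with no
p-value.

## Feature comparisons

Length, GC fraction and forward-strand CpG density (CG dinucleotides per
nt) over the full intron span are compared between retained and
non-retained introns with Welch's t-test (pooled-variance Student behind a
flag). Gene clustering is tested by comparing pairwise edge-to-edge
distances between same-chromosome IR-gene pairs against randomly drawn
same-chromosome pairs; note the pairwise distances within a set share genes
and are therefore dependent, which makes this t-test mildly
anti-conservative under the null (measured ≈0.17 rejection at α = 0.05 in a
null simulation) — its p-values should be read as descriptive unless they
are many orders of magnitude below the threshold. Within-gene adjacency of
retained introns uses a permutation null that preserves each gene's intron
count and number of retained introns (≥ 1,000 draws, add-one resampling
p). IR vs expression is an OLS of log expression on IR level with the
slope's F-test.

## Simulator

The simulator emits a random-sequence genome with planted multi-exon genes
on both strands, spliced/retaining fragments as coordinate-sorted SAM,
per-CpG count tables and ChIP tiles, plus a ground-truth table. Defaults:
10 genes of 3 exons (400–800 nt) separated by introns of 150–400 nt, 2,000
single-end 100-nt fragments per gene, per-intron true retention drawn
uniform on [0, 0.8], CpG coverage Poisson(30), baseline beta 0.8 with a 0.3
dip within 100 bp of retained-intron junctions and midpoints, and ChIP fold
enrichment 4.0 dipping to 2.0 over the same regions. Exonic length
dominates intron length as in mammalian mRNA, which keeps the IR estimator's
length-ratio bias small; retention is defined at the transcript-molecule
level and fragments are drawn length-weighted across the 2^k joint
retention isoforms of each gene, the sampling model of a shotgun library.

Deliberately not modelled: sequencing error, bisulfite conversion failure,
fragment-length dispersion, positional coverage bias, multi-mapping reads
in the RNA-seq input, and transcript-abundance heterogeneity between genes.
Passing tests therefore demonstrate correctness of the measurement and
inference machinery under clean sampling assumptions, not robustness to
alignment artefacts or library biases in real data.

## Numerical choices

- Trim count ⌊0.30·n⌋ per side (floor): deterministic and exact for the
  small depth vectors of toy introns.
- Intronic abundance is rounded half-up before the count test, which
  requires integers.
- The exact-test oracle in the test suite uses integer/rational arithmetic
  (equal totals: P(Y≤y|x) = Σ C(x+j,j)·2^(y−j) / 2^(x+y+1), built by
  recurrence) and an independent negative-binomial route; the log-space
  implementation matches both to 1e−9 over the full x, y ≤ 200 grid.
- Mask granularity is per base; maximal runs of failing bases are merged
  into BED intervals.
- Window assignment uses floor division on the transcription-oriented
  offset; the minus-strand flip is an involution (applying it twice
  restores the genomic assignment).
- Degenerate inputs are surfaced, not silenced: empty measurable regions
  and 0/0 ratios propagate as not-assessable; constant-difference paired
  tests and constant-group comparisons raise.

## Problem sizes

Test-suite and acceptance runs use toy scales chosen to exercise every code
path with tight statistical margins: 1.2–2.5 kb genomes for
mappability-oracle equivalence, 200 replicates × 5,000 fragments for IR
recovery at r = 0.3, a 50-intron two-sample contrast (Δr = 0.25) for
end-to-end differential recovery, and 2,000-intron null simulations for
type-I control. The full suite completes in well under a minute on one CPU.

## Known limitations

- The brute-force aligner is quadratic in genome size and intended for
  genomes up to tens of kilobases; real genomes go through the
  FASTA-export / external-aligner / SAM-import path.
- The per-intron normalization of the count test treats the local fragment
  pool as the sampling frame; a library-size frame would weight strong
  expression changes differently. Both are exposed, neither is "the"
  answer.
- The gene-distance t-test's dependence caveat above.
- Single-transcript genes in the simulator; the quantifier itself handles
  multi-transcript annotations, but simulated truth does not exercise
  alternative splice-site use.
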