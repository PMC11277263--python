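# Methods

## Coordinate and data model

All internal coordinates are 0-based, half-open along the transcript; report
files use 1-based inclusive positions (GFF3 convention), while the alignment
TSV keeps BED-style 0-based 5′ starts. Transcript sequences are stored
5′→3′; there is no strand downstream of projection, because every quantity
the package computes is transcript-relative. Alignments arrive as a
transcript-space TSV (`transcript_id  start5  length  count`) rather than
genome-space BAM: this removes the aligner dependency and matches how the
per-transcript statistics are defined. Footprint lengths are restricted to
23–36 nt at ingestion (library-prep cutoff); transcripts whose CDS is not a
multiple of 3 or falls outside the sequence are rejected at read time with
the offending ids reported.

## P-site geometry and metagene diagnostics

Each footprint is reduced to a single P-site base at `start5 + offset(length)`.
Offsets are estimated per length (riboWaltz-style) as the negated argmax of
the 5′-end metagene in the window [−18, −6] relative to start codons — the
initiation peak — with ties broken toward the smaller offset and a
reliability rule: the peak must exceed twice the window mean and the length
must have ≥ 200 reads, otherwise the canonical default of 12 nt is used and
the length flagged. Frame periodicity is the distribution of P-sites over
the three codon frames, restricted to the CDS. Metagene profiles anchor at
the first base of the start codon or of the stop codon and exclude
transcripts that cannot contain the full window; raw summing is the default,
with per-transcript-mean normalization available to prevent dominance by
highly expressed transcripts.

The package defaults to offset P-sites for pause-site anchoring (rather
than raw 5′ ends); a `five_prime` site-mode is exposed for comparison since
published analyses are not always explicit about which anchor they use.

## Pause score, z-standardization, and calling

The score at position *i* is `depth[i]` divided by the mean depth of the
window `max(0, i−(W−1)/2) … min(L−1, i+(W−1)/2)` (window includes *i*;
default W = 1,000 nt, consistent with the published sliding-window pause
metric this reproduces — under uniform coverage the score is ≈ 1, which is
what makes a cutoff of 50 meaningful). Only positions with nonzero depth are
scored. Scores are then z-standardized within coverage bins — deciles of
window read totals, 10 bins by default — using the sample standard deviation
(ddof = 1); singleton or zero-variance bins get z = 0 with a warning. A site
is *called* when score > 50, z > 1.65 and depth > 20, all strict
inequalities; "depth" here is the P-site depth at the position in the active
site-mode. Pause analysis operates on replicate-merged coverage; the
functions accept any coverage profile, so per-replicate calling is possible
by simply not merging.

For time-series analysis the per-transcript maximum score at each time point
(0 when nothing is scored) forms the pause matrix, restricted to transcripts
called at ≥ 1 time point. Rows are z-scored across time points (so clusters
capture dynamics shape, not magnitude) and clustered by k-means with a fixed
seed, k = 5 by default — the number of dynamics classes distinguishable in
dark-to-light time courses; labels are relabeled by descending cluster size
for stability, and Ward hierarchical clustering is available as an
alternative. Fewer distinct profiles than k triggers an automatic reduction
with a warning.

## Translation metrics

*Normalization* is median-of-ratios over genes positive in all samples.
*Differential expression* uses group means of normalized counts with a 0.5
pseudocount for log₂FC, and either a Wald test with a pooled
method-of-moments negative-binomial dispersion (default) or an exact
conditional Poisson (binomial) test; significance is the dual filter
|log₂FC| > 1 ∧ p < 0.05 on raw p-values, with RPF assays additionally
requiring a mean raw count ≥ 5. This is a transparent stand-in for a full
GLM engine: the package's downstream decisions use only the filter, not
shrinkage estimates.

*Translation efficiency* is the ratio of TPM-like RPF density to RNA density
over the CDS (CDS-restricted lengths; genes below an expression floor or
with zero RNA signal are masked). ΔTE between conditions is
log₂(TE_B/TE_A) standardized robustly across genes,
z = (x − median)/(1.4826·MAD), significant at |z| > 1.5 (strict). A
transparent ratio-plus-robust-z replaces posterior-based ΔTE engines on
purpose — determinism and testability over model sophistication.

*Translation intensity* is TI = Median × Coverage, where n is the number of
region bases with depth > 0, Coverage = n / region length, and Median is the
standard median of the covered depths (even n averages the two central
values — the package deliberately implements the standard median, reading
the non-halved even-branch sometimes printed for this statistic as a typo
against its own definition "median depth of covered bases"). The region
defaults to the CDS; a transcript-length denominator is available since both
conventions appear in the field. Invariants: 0 ≤ Coverage ≤ 1,
TI ≤ Median, TI = 0 iff nothing is covered.

*Group comparisons* use the two-sided Wilcoxon rank-sum test: the exact
distribution for untied samples of ≤ 20 per group, otherwise the normal
approximation with tie correction (no continuity correction, so identical
groups give p = 1).

## Sequence features

Context logos are position probability matrices over a ±30 nt window around
anchors (incomplete windows dropped and tallied), pseudocount 0 by default.
GC metaplots come in two scales: mean GC per absolute position within ±500 nt
of the anchor (full flanks required), and a length-scaled profile cutting
start-codon→anchor and anchor→stop-codon into 50 equal-width bins each (the
last bin absorbs the remainder; anchors at the CDS start are an error, and
segments shorter than 50 nt are dropped and tallied). Nascent-peptide
context maps a nucleotide anchor on any of a codon's three bases to that
codon, translates in the CDS frame, and reports amino-acid frequencies plus
net charge with K, R = +1, D, E = −1, H = 0 at physiological pH (the map is
configurable).

PWM scanning uses log₂ odds against a 0-order background composition with an
ε = 10⁻³ pseudo-probability inside the logarithm. Scores are discretized to
an integer lattice (milli-bit granularity) *shared* between scanning and the
score-distribution dynamic program, so hit p-values — tail probabilities of
the lattice score under the background — are exact with respect to the
scanned scores; the DP is a per-column convolution of the score distribution
and matches exhaustive enumeration bit-for-bit on small motifs. A 0-order
background keeps the exact DP tractable; higher-order backgrounds are a
documented extension point, and de-novo motif discovery is out of scope — the
shipped 16-column PPM encodes the repeated CGC consensus
(`CGCCGCCGCCGCCGCC`, 0.85/0.05 column weights, a synthetic stand-in for a
discovery-derived frequency matrix). The motif–pausing association compares
maximum pausing scores of motif-bearing vs motif-free transcripts (paused
transcripts by default) by rank-sum.

Ensemble free energy delegates to the ViennaRNA partition function at 37 °C
with the standard nearest-neighbor parameters (T mapped to U). Reverse
complements are *not* expected to fold to the same energy; both strands can
be evaluated explicitly when that matters.

## Synthetic-data generator

The generator is a pure function of its config (which carries the seed);
fixed seed ⇒ byte-identical outputs. It emulates:

- **Transcripts**: 5′UTR/CDS/3′UTR with lengths drawn from configured ranges
  (defaults 60–120 nt UTRs, 120–260 codons), per-position GC probability
  with a base level (0.50), a 5′→3′ downward gradient (−0.10 across the
  transcript, the decrease typically seen toward stop codons) and a +0.08
  offset for paused transcripts; ATG/TAA planted, internal stops scrubbed.
- **Pauses**: a fraction of transcripts (default 0.3) get one pause codon in
  the central third of the CDS with sampling-weight multiplier λ (default
  200) and optional downstream depletion d ∈ (0, 1] modeling run-off
  scarcity; pauses are codon-granular because ribosome dwell is codon-level.
  A C is planted at −13 with probability 0.6 and the CGC motif overwritten
  12 nt downstream of the pause.
- **Footprints**: P-sites drawn codon-wise (initiation codon boosted 5× to
  create the start peak the offset estimator relies on), frame fidelity 0.9,
  lengths 27–31 nt at (0.15, 0.2, 0.3, 0.2, 0.15), 5′ end = P-site − 12 for
  every length; exactly n_reads footprints are emitted (multinomial
  allocation), and footprints that would overrun an end are clamped.
- **Dynamics**: five time points with archetype profiles — "released"
  (paused only in darkness) and "spike" (transient pause at the first light
  time point) — scaling the excess dwell per time point.
- **Counts and protein**: negative-binomial gene counts (dispersion 0.05)
  with planted fold changes in the second half of samples; protein
  abundance = base × dwell^(−γ) × lognormal noise (γ = 1 couples pausing
  negatively to protein; γ = 0 makes groups exchangeable).

What the generator does **not** emulate: sequencing errors and base
qualities, rRNA contamination, multi-isoform genes, uORF translation,
codon-usage-driven dwell variation, and genome-space alignment artifacts.
Passing tests therefore demonstrate that the statistics recover the signals
they are defined on when those signals are present in clean
transcript-space data — not that any particular biological dataset contains
them.

## Numerical choices and problem sizes

Scores and TI are exact integer/float arithmetic with no tolerance knobs;
the only discretization is the PWM milli-bit lattice (granularity 10⁻³ bits,
far below any decision threshold at p ≤ 10⁻⁴). Tests run the generator at
modest sizes chosen to make the assertions statistically comfortable while
keeping the suite fast: 200 transcripts × 400k reads for pause recovery,
20 seeds × 200 transcripts × 100k reads for the TI/protein coupling checks,
600 long-CDS transcripts for the GC/logo recovery, 4⁶ exhaustive enumeration
for PWM exactness. Recovery assertions use 3–4σ sampling bands at those
sizes.

## Known limitations

- The DE and ΔTE engines are deliberately transparent approximations; they
  are not numerically interchangeable with shrinkage-based GLM tools.
- The exact-p-value DP assumes a 0-order background and position
  independence.
- Pause calling assumes single-isoform transcript models and merged
  replicates; the per-replicate path exists but is unexercised by defaults.
- The offset estimator needs an initiation peak; libraries depleted of
  initiating ribosomes (e.g. harringtonine run-off) will fall back to the
  12-nt default.
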