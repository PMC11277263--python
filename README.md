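# ribopause

Ribosome-pausing analysis for Ribo-seq data.

Ribosome profiling sequences the ~27–31 nt mRNA fragments protected by
translating ribosomes (RPFs). When a ribosome dwells on a codon — because of
mRNA secondary structure, nascent-peptide interactions, or regulatory
signals — footprints pile up at that position and become scarce elsewhere on
the transcript, repressing protein output. `ribopause` is a toolkit for
detecting and characterizing such pause events from footprint alignments in
transcript coordinates, aimed at researchers analyzing translational
regulation (for example in etiolated plant seedlings responding to light).

## What it computes

**P-site diagnostics.** Per-length 5′-end → P-site offsets estimated from the
initiation peak upstream of annotated start codons, footprint length
histograms, 3-nt frame periodicity, and metagene profiles around start/stop
codons.

**Pause detection.** For each covered position *i*, the pausing score

&nbsp;&nbsp;&nbsp;&nbsp;score(*i*) = depth(*i*) / mean depth over a window centered on *i*

(window 1,000 nt by default, clipped at transcript ends, including *i*), so
uniform coverage scores ≈ 1. Scores are z-standardized within coverage bins
(deciles of window read totals), and a site is called paused when
score > 50, z > 1.65 and depth > 20 (all strict). Per-transcript maximum
scores across time points form a pause matrix that is clustered (k-means,
k = 5 by default; Ward hierarchical available) into pausing-dynamics classes.

**Translation metrics.** Median-of-ratios count normalization, differential
expression with the dual filter |log₂FC| > 1 ∧ p < 0.05 (plus a mean-≥5-reads
floor for RPF counts), translation efficiency TE = RPF density / RNA density
with robust ΔTE z-scores (significant at |z| > 1.5), and the coverage-aware
translation intensity

&nbsp;&nbsp;&nbsp;&nbsp;TI = Median(depth over covered bases) × Coverage,&nbsp;&nbsp; Coverage = n / Length,

which stays low for transcripts whose reads are concentrated at one pause
site even when TE looks normal. Group contrasts (paused vs unpaused TI,
protein abundance) use the two-sided Wilcoxon rank-sum test.

**Pause-site sequence features.** Nucleotide logos of the pause-site context
(e.g. the C enrichment 13 nt upstream), GC metaplots at ±500 nt and on a
length-scaled 50+50-bin axis, nascent-peptide amino-acid/charge context, PWM
scanning of the repeated CGC motif (`CGCCGCCGCCGCCGCC`) with *exact* hit
p-values computed by dynamic programming over the log-odds score lattice, and
ensemble (partition-function) free energies of candidate stem-loops via the
ViennaRNA engine.

**Synthetic data.** A fully seeded generator plants every signal the analysis
looks for — pause codons with elevated dwell, downstream run-off depletion,
GC offsets, the −13 C, the CGC motif, archetype-driven pause dynamics over
five time points, matched RNA/RPF counts and a pausing-coupled protein
table — so the whole pipeline is testable against known ground truth.

## Worked example

```python
import pandas as pd
from ribopause import (SimulationConfig, AnalysisConfig, generate_transcriptome,
                       simulate_rpf_library, build_coverage_all,
                       estimate_psite_offsets, frame_periodicity,
                       score_timepoint, translation_intensity,
                       compare_groups, ensemble_free_energy)

cfg = SimulationConfig(n_transcripts=60, seed=7, depletion=0.5)
models, truth = generate_transcriptome(cfg)
txs = {m.transcript_id: m for m in models}
lib = simulate_rpf_library(models, truth, cfg, 120_000)

est = estimate_psite_offsets(lib, txs)
fs = frame_periodicity(lib, txs, est.offsets)
profiles = build_coverage_all(lib, txs, "psite", est.offsets)
sites = score_timepoint(profiles, AnalysisConfig())
called = [s for s in sites if s.called]

ti = pd.Series({tid: translation_intensity(p, txs[tid]).ti
                for tid, p in profiles.items()})
a = ti[truth.index[truth["paused"]]]; b = ti[truth.index[~truth["paused"]]]
```

With the results printed (offsets, frame fractions, call counts, the
rank-sum comparison of TI between groups, and the motif's folding energy),
this session shows:

```
offsets: {27: 12, 28: 12, 29: 12, 30: 12, 31: 12}
frame fractions: (0.900, 0.050, 0.050)
called pause sites: 18 on 18 transcripts (planted: 18)
median TI paused 0.77 vs unpaused 2.06, rank-sum p = 1.25e-03
CGC motif ensemble dG = -2.95 kcal/mol
```

The estimator recovers the planted 12-nt offset for every footprint length
and the planted 90 % frame fidelity; all 18 planted pauses are called at the
operating cutoffs with no false positives; the paused group's translation
intensity is significantly lower (the run-off depletion at work); and the CGC
motif folds into a stem-loop with an ensemble free energy of −2.95 kcal/mol.

There is also a CLI (`ribopause simulate|metagene|pauses|cluster|metrics|
features|run-all`); `ribopause run-all --seed 3 --outdir out/` executes the
full synthetic pipeline and writes a run manifest.

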