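"""Synthetic Ribo-seq data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
transcript models with 5'UTR/CDS/3'UTR and a 5'->3' GC gradient, footprint
libraries with 27-31 nt lengths, codon-level P-site placement with
configurable frame fidelity and a fixed 5'-end->P-site geometry, planted
pause codons with elevated dwell (and optional downstream run-off
depletion), matched negative-binomial RNA-seq/RPF gene counts, and a
protein table coupled negatively to planted pausing.  Every generator is a
pure function of (config, seed): a fixed seed reproduces outputs byte for
byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountTable,
    RpfAlignment,
    TranscriptModel,
    write_alignments,
    write_counts,
    write_transcriptome,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: per-timepoint multiplier applied to the planted excess dwell, per dynamics
#: archetype: "released" pauses are strong in darkness and vanish on light
#: exposure; "spike" pauses appear transiently at the first light timepoint.
ARCHETYPE_PROFILES: dict[str, tuple[float, ...]] = {
    "released": (1.0, 0.0, 0.0, 0.0, 0.0),
    "spike": (0.0, 1.0, 0.0, 0.0, 0.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    n_transcripts: int = 200
    utr5_range: tuple[int, int] = (60, 120)
    cds_codon_range: tuple[int, int] = (120, 260)
    utr3_range: tuple[int, int] = (60, 120)

    gc_base: float = 0.50
    gc_slope: float = -0.10           # GC drifts down 5'->3' across a transcript
    gc_offset_paused: float = 0.08    # paused transcripts are GC-richer overall

    rpf_length_probs: dict[int, float] = field(
        default_factory=lambda: {27: 0.15, 28: 0.20, 29: 0.30, 30: 0.20, 31: 0.15}
    )
    frame_fidelity: float = 0.9       # P(P-site lands on the codon first base)
    psite_offsets: dict[int, int] = field(
        default_factory=lambda: {n: 12 for n in range(27, 32)}
    )
    start_codon_boost: float = 5.0    # initiation-site occupancy peak
    expression_sigma: float = 1.0     # lognormal spread of transcript expression

    paused_fraction: float = 0.3
    dwell: float = 200.0              # sampling-weight multiplier at the pause codon
    depletion: float = 1.0            # run-off factor for codons downstream of a pause
    timepoints: tuple[str, ...] = ("0h", "0.5h", "1h", "2h", "4h")
    archetype_probs: dict[str, float] = field(
        default_factory=lambda: {"released": 0.7, "spike": 0.3}
    )

    plant_motif: bool = True
    motif: str = "CGCCGCCGCCGCCGCC"
    motif_offset: int = 12            # nt downstream of the pause site
    motif_prob: float = 1.0           # P(motif | paused)
    c13_prob: float = 0.6             # P(C planted at -13 | paused)

    rna_mean: float = 200.0           # baseline RNA count per gene per sample
    dispersion: float = 0.05          # NB dispersion alpha (var = mu + alpha mu^2)
    de_fraction: float = 0.1
    de_fold: float = 4.0
    te_fraction: float = 0.0          # fraction of genes with planted TE shifts
    te_fold: float = 4.0

    protein_base: float = 1000.0
    protein_gamma: float = 1.0        # protein ~ dwell^(-gamma)
    protein_sigma: float = 0.25       # lognormal noise, log-space sd

    seed: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.rpf_length_probs.values()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("rpf_length_probs must sum to 1")
        if self.dwell < 1:
            raise ValueError("dwell factor must be >= 1")
        if not (0 < self.depletion <= 1):
            raise ValueError("depletion must be in (0, 1]")
        if not (0 <= self.frame_fidelity <= 1):
            raise ValueError("frame_fidelity must be in [0, 1]")
        lo = self.gc_base - abs(self.gc_slope) / 2
        hi = self.gc_base + self.gc_offset_paused + abs(self.gc_slope) / 2
        if lo <= 0.02 or hi >= 0.98:
            raise ValueError(
                f"infeasible GC configuration: per-position GC spans [{lo:.2f}, {hi:.2f}]")
        ap = np.array(list(self.archetype_probs.values()))
        if abs(ap.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_probs must sum to 1")


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _sample_bases(rng: np.random.Generator, p_gc: np.ndarray) -> np.ndarray:
    """Draw a base per position: GC with probability p_gc, strands balanced."""
    gc = rng.random(p_gc.size) < p_gc
    half = rng.random(p_gc.size) < 0.5
    out = np.empty(p_gc.size, dtype="<U1")
    out[gc & half] = "G"
    out[gc & ~half] = "C"
    out[~gc & half] = "A"
    out[~gc & ~half] = "T"
    return out


def _scrub_stops(cds: np.ndarray) -> None:
    """Replace internal stop codons in place (T->C at the wobble-free first base)."""
    for i in range(3, cds.size - 3, 3):
        if "".join(cds[i:i + 3]) in STOP_CODONS:
            cds[i] = "C"


def generate_transcriptome(config: SimulationConfig
                           ) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate transcript models plus the planted-truth table.

    The truth table has one row per transcript: paused flag, 0-based pause
    position (first base of the pause codon; -1 if unpaused), dwell factor,
    dynamics archetype, motif / C-at--13 flags, expression rate and true TE
    multiplier.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    n_paused = int(round(config.paused_fraction * n))

    arch_names = list(config.archetype_probs)
    arch_p = np.array([config.archetype_probs[a] for a in arch_names])

    expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=n)
    n_te = int(round(config.te_fraction * n))
    te_mult = np.ones(n)
    if n_te:
        te_idx = rng.choice(n, size=n_te, replace=False)
        te_mult[te_idx] = config.te_fold

    models: list[TranscriptModel] = []
    rows = []
    for i in range(n):
        tid = f"tx{i + 1:04d}"
        gid = f"gene{i + 1:04d}"
        paused = i < n_paused
        utr5 = int(rng.integers(*config.utr5_range, endpoint=True))
        ncod = int(rng.integers(*config.cds_codon_range, endpoint=True))
        utr3 = int(rng.integers(*config.utr3_range, endpoint=True))
        L = utr5 + 3 * ncod + utr3

        pos = np.arange(L)
        p_gc = config.gc_base + (config.gc_offset_paused if paused else 0.0) \
            + config.gc_slope * (pos / L - 0.5)
        seq = _sample_bases(rng, np.clip(p_gc, 0.02, 0.98))

        cds_start, cds_end = utr5, utr5 + 3 * ncod
        seq[cds_start:cds_start + 3] = list("ATG")
        seq[cds_end - 3:cds_end] = list("TAA")
        _scrub_stops(seq[cds_start:cds_end])

        pause_pos = -1
        dwell = 1.0
        archetype = ""
        motif = False
        c13 = False
        if paused:
            lo, hi = ncod // 3, 2 * ncod // 3
            pause_codon = int(rng.integers(lo, hi))
            pause_pos = cds_start + 3 * pause_codon
            dwell = config.dwell
            archetype = arch_names[int(rng.choice(len(arch_names), p=arch_p))]
            if rng.random() < config.c13_prob:
                seq[pause_pos - 13] = "C"
                c13 = True
            if config.plant_motif and rng.random() < config.motif_prob:
                m0 = pause_pos + config.motif_offset
                seq[m0:m0 + len(config.motif)] = list(config.motif)
                motif = True
                _scrub_stops(seq[cds_start:cds_end])

        models.append(TranscriptModel(tid, "".join(seq), cds_start, cds_end, gid))
        rows.append(dict(transcript_id=tid, gene_id=gid, paused=paused,
                         pause_pos=pause_pos, dwell=dwell, archetype=archetype,
                         motif=motif, c13=c13,
                         expression=expr[i], te_multiplier=te_mult[i]))

    truth = pd.DataFrame(rows).set_index("transcript_id")
    return models, truth


# ---------------------------------------------------------------------------
# RPF library
# ---------------------------------------------------------------------------

def simulate_rpf_library(transcripts: Sequence[TranscriptModel],
                         truth: pd.DataFrame,
                         config: SimulationConfig,
                         n_reads: int,
                         rng: np.random.Generator | None = None,
                         dwell_override: Mapping[str, float] | None = None,
                         ) -> list[RpfAlignment]:
    """Sample a footprint library of exactly ``n_reads`` footprints.

    P-sites are drawn codon-wise: uniform over CDS codons, boosted at the
    initiation codon, multiplied by the dwell factor at a planted pause
    codon and by the depletion factor downstream of it.  The footprint 5'
    end is the P-site minus the configured offset for its sampled length;
    with frame fidelity f the P-site lands on the codon first base with
    probability f, else on base +1 or +2 of the codon.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in truth.index]
    if missing:
        raise ValueError(f"truth table missing transcripts: {missing[:3]}...")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lengths = np.array(sorted(config.rpf_length_probs))
    length_p = np.array([config.rpf_length_probs[l] for l in lengths])
    f = config.frame_fidelity
    frame_p = np.array([f, (1 - f) / 2, (1 - f) / 2])

    expr = truth.loc[[t.transcript_id for t in transcripts], "expression"].to_numpy()
    tx_reads = rng.multinomial(n_reads, expr / expr.sum())

    out: dict[tuple[str, int, int], int] = {}
    for tx, reads in zip(transcripts, tx_reads):
        if reads == 0:
            continue
        row = truth.loc[tx.transcript_id]
        ncod = tx.cds_length // 3
        w = np.ones(ncod)
        w[0] *= config.start_codon_boost
        dwell = (dwell_override.get(tx.transcript_id, row["dwell"])
                 if dwell_override is not None else row["dwell"])
        if row["paused"]:
            pc = (int(row["pause_pos"]) - tx.cds_start) // 3
            w[pc] *= dwell
            w[pc + 1:] *= config.depletion
        codon_counts = rng.multinomial(reads, w / w.sum())
        hot = np.nonzero(codon_counts)[0]
        for c in hot:
            k = int(codon_counts[c])
            frames = rng.multinomial(k, frame_p)
            for fr in np.nonzero(frames)[0]:
                kk = int(frames[fr])
                psite = tx.cds_start + 3 * c + fr
                lens = rng.multinomial(kk, length_p)
                for li in np.nonzero(lens)[0]:
                    ln = int(lengths[li])
                    start5 = psite - config.psite_offsets[ln]
                    # clamp footprints that would overrun transcript ends
                    start5 = min(max(start5, 0), len(tx) - ln)
                    key = (tx.transcript_id, start5, ln)
                    out[key] = out.get(key, 0) + int(lens[li])
    return [RpfAlignment(t, s, l, c) for (t, s, l), c in sorted(out.items())]


def simulate_time_series(transcripts: Sequence[TranscriptModel],
                         truth: pd.DataFrame,
                         config: SimulationConfig,
                         n_reads: int,
                         ) -> dict[str, list[RpfAlignment]]:
    """One footprint library per timepoint with archetype-driven pause dynamics.

    The excess dwell of a paused transcript at timepoint t is the planted
    dwell scaled by its archetype profile: dwell_t = 1 + (dwell-1)*profile[t].
    """
    libs: dict[str, list[RpfAlignment]] = {}
    for ti, tp in enumerate(config.timepoints):
        dwell_tp: dict[str, float] = {}
        for tid, row in truth.iterrows():
            if not row["paused"]:
                continue
            prof = ARCHETYPE_PROFILES.get(row["archetype"])
            mult = prof[ti % len(prof)] if prof is not None else 1.0
            dwell_tp[tid] = 1.0 + (row["dwell"] - 1.0) * mult
        rng = np.random.default_rng([config.seed, 1000 + ti])
        libs[tp] = simulate_rpf_library(transcripts, truth, config, n_reads,
                                        rng=rng, dwell_override=dwell_tp)
    return libs


# ---------------------------------------------------------------------------
# RNA-seq / RPF gene counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        raise ValueError("dispersion must be positive")
    if alpha < 1e-6:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_rna_counts(transcripts: Sequence[TranscriptModel],
                        truth: pd.DataFrame,
                        config: SimulationConfig,
                        n_samples: int,
                        assay: str = "rna",
                        rng: np.random.Generator | None = None,
                        ) -> CountTable:
    """Negative-binomial gene counts, genes x samples.

    The second half of the samples forms a "treated" group in which a
    ``de_fraction`` of genes carry a planted ``de_fold`` change.  For the
    ``rpf`` assay, means are additionally scaled by each gene's true TE
    multiplier so that planted translation shifts are recoverable.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 77 if assay == "rna" else 78])
    genes = [truth.loc[t.transcript_id, "gene_id"] for t in transcripts]
    mu0 = config.rna_mean * truth["expression"].to_numpy() \
        / truth["expression"].mean()
    if assay == "rpf":
        mu0 = mu0 * truth["te_multiplier"].to_numpy()

    n = len(genes)
    n_de = int(round(config.de_fraction * n))
    de = np.zeros(n, dtype=bool)
    de[rng.choice(n, size=n_de, replace=False) if n_de else []] = True

    cols = {}
    half = n_samples // 2
    for j in range(n_samples):
        mu = mu0 * np.where(de & (j >= half), config.de_fold, 1.0)
        cols[f"{assay}_s{j + 1:02d}"] = _nb_draw(rng, mu, config.dispersion)
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return CountTable(df, assay=assay)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# protein table
# ---------------------------------------------------------------------------

def simulate_protein_table(truth: pd.DataFrame,
                           config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           ) -> pd.DataFrame:
    """Protein abundance negatively coupled to planted ribosome dwell.

    abundance = base * dwell^(-gamma) * lognormal noise; with gamma = 0 the
    paused and unpaused groups are exchangeable.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 99])
    dwell = np.where(truth["paused"], truth["dwell"], 1.0).astype(float)
    noise = rng.lognormal(0.0, config.protein_sigma, size=len(truth))
    abundance = config.protein_base * dwell ** (-config.protein_gamma) * noise
    return pd.DataFrame(
        {"gene_id": truth["gene_id"].to_numpy(), "abundance": abundance},
        index=truth.index,
    )


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, outdir: str | Path,
                     n_reads: int = 100_000, n_samples: int = 6) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, truth = generate_transcriptome(config)
    paths: dict[str, Path] = {
        "fasta": outdir / "transcripts.fa",
        "gff3": outdir / "transcripts.gff3",
        "truth": outdir / "truth.tsv",
        "rna_counts": outdir / "rna_counts.tsv",
        "rpf_counts": outdir / "rpf_counts.tsv",
        "protein": outdir / "protein.tsv",
    }
    write_transcriptome(models, paths["fasta"], paths["gff3"])
    truth.sort_index().to_csv(paths["truth"], sep="\t")
    libs = simulate_time_series(models, truth, config, n_reads)
    for tp, aligns in libs.items():
        p = outdir / f"alignments_{tp.replace('.', '_')}.tsv"
        write_alignments(aligns, p)
        paths[f"alignments_{tp}"] = p
    write_counts(simulate_rna_counts(models, truth, config, n_samples, "rna"),
                 paths["rna_counts"])
    write_counts(simulate_rna_counts(models, truth, config, n_samples, "rpf"),
                 paths["rpf_counts"])
    simulate_protein_table(truth, config).sort_index().to_csv(
        paths["protein"], sep="\t")
    return paths
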