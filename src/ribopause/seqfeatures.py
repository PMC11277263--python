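"""Sequence features of pause sites: logos, GC metaplots, nascent-peptide
context, PWM motif scanning with exact p-values, stem-loop free energy.

The motif machinery scans a position probability matrix (PPM) converted to
log-odds against a 0-order background; hit p-values are exact tail
probabilities of the log-odds score under the background, computed by
dynamic programming on an integer score lattice (milli-bit granularity)
shared between scanning and the DP, so scan scores and the score
distribution live on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import TranscriptModel

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: log-odds pseudo-probability added inside the log to avoid -inf
LOG_ODDS_EPS = 1e-3
#: integer lattice granularity for exact score-distribution DP (milli-bits)
SCORE_SCALE = 1000

#: net-charge contribution per residue at physiological pH
DEFAULT_CHARGE_MAP = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.0}

#: anchor = (transcript_id, 0-based transcript position)
Anchor = tuple[str, int]


# ---------------------------------------------------------------------------
# position probability matrices
# ---------------------------------------------------------------------------

@dataclass
class PositionProbabilityMatrix:
    """Per-position base probabilities over {A, C, G, T}; columns sum to 1."""

    probs: np.ndarray                    # shape (4, n_positions), rows A,C,G,T
    positions: np.ndarray                # relative coordinates of the columns
    pseudocount: float = 0.0
    n_sequences: int = 0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.probs.shape[0] != 4:
            raise ValueError("PPM must have 4 rows (A, C, G, T)")
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")
        col_sums = self.probs.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("PPM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(BASES), columns=self.positions)

    def log_odds_lattice(self, background: np.ndarray) -> np.ndarray:
        """Integer-scaled log2 odds, shape (4, width): round(1000 * log2((p+eps)/q))."""
        q = np.asarray(background, dtype=float)[:, None]
        lo = np.log2((self.probs + LOG_ODDS_EPS) / q)
        return np.round(lo * SCORE_SCALE).astype(np.int64)


def pwm_from_sequences(segments: Sequence[str], pseudocount: float = 0.0,
                       positions: Sequence[int] | None = None,
                       ) -> PositionProbabilityMatrix:
    """Build a PPM from aligned, equal-length sequence segments."""
    if not segments:
        raise ValueError("no segments")
    width = len(segments[0])
    if any(len(s) != width for s in segments):
        raise ValueError("segments must be aligned (equal length)")
    counts = np.zeros((4, width))
    for s in segments:
        s = s.upper().replace("U", "T")
        for j, b in enumerate(s):
            if b in BASE_INDEX:
                counts[BASE_INDEX[b], j] += 1
    counts += pseudocount
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a column has no counts; use a pseudocount")
    if positions is None:
        positions = np.arange(1, width + 1)
    return PositionProbabilityMatrix(counts / totals, np.asarray(positions),
                                     pseudocount, len(segments))


def write_ppm(ppm: PositionProbabilityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#PPM n={ppm.n_sequences}\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{p:.6f}" for p in ppm.probs[i]) + "\n")


def read_ppm(path: str | Path) -> PositionProbabilityMatrix:
    n_seq = 0
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#PPM"):
                n_seq = int(line.split("n=")[1])
                continue
            parts = line.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
    probs = np.array([rows[b] for b in BASES])
    probs /= probs.sum(axis=0)       # re-normalize away rounding in the file
    return PositionProbabilityMatrix(probs, np.arange(1, probs.shape[1] + 1),
                                     n_sequences=n_seq)


def cgc_motif_ppm() -> PositionProbabilityMatrix:
    """The shipped 16-column PPM whose consensus is the repeated CGC motif."""
    with resources.as_file(
            resources.files("ribopause").joinpath("data/cgc_motif.ppm")) as p:
        return read_ppm(p)


# ---------------------------------------------------------------------------
# context logo
# ---------------------------------------------------------------------------

def context_logo(transcripts: Mapping[str, TranscriptModel],
                 anchors: Iterable[Anchor],
                 window: tuple[int, int] = (-30, 30),
                 pseudocount: float = 0.0,
                 ) -> PositionProbabilityMatrix:
    """Base-probability matrix of the sequence context around anchor sites.

    Anchors whose window would run off the transcript are dropped (their
    number is recorded as the difference from the input count).
    """
    lo, hi = window
    width = hi - lo + 1
    counts = np.zeros((4, width))
    n_used = 0
    for tid, pos in anchors:
        tx = transcripts.get(tid)
        if tx is None or pos + lo < 0 or pos + hi >= len(tx):
            continue
        seg = tx.sequence[pos + lo:pos + hi + 1]
        for j, b in enumerate(seg):
            if b in BASE_INDEX:
                counts[BASE_INDEX[b], j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no anchor has a complete window")
    counts += pseudocount
    probs = counts / counts.sum(axis=0)
    return PositionProbabilityMatrix(probs, np.arange(lo, hi + 1),
                                     pseudocount, n_used)


# ---------------------------------------------------------------------------
# GC metaplots
# ---------------------------------------------------------------------------

@dataclass
class GcMetaplot:
    mode: Literal["absolute", "scaled"]
    positions: np.ndarray     # relative positions (absolute) or bin index (scaled)
    values: np.ndarray        # mean GC fraction per position/bin, in [0, 1]
    n_anchors: int
    n_dropped: int = 0


def _is_gc(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return (arr == ord("G")) | (arr == ord("C"))


def gc_absolute(transcripts: Mapping[str, TranscriptModel],
                anchors: Iterable[Anchor], flank: int = 500) -> GcMetaplot:
    """Mean GC per absolute position within +/-flank nt of each anchor.

    Only anchors with both flanks fully inside the transcript contribute.
    """
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_used = n_dropped = 0
    for tid, pos in anchors:
        tx = transcripts.get(tid)
        if tx is None or pos - flank < 0 or pos + flank >= len(tx):
            n_dropped += 1
            continue
        acc += _is_gc(tx.sequence[pos - flank:pos + flank + 1])
        n_used += 1
    if n_used == 0:
        raise ValueError("no anchor has full flanks")
    return GcMetaplot("absolute", np.arange(-flank, flank + 1), acc / n_used,
                      n_used, n_dropped)


def gc_scaled(transcripts: Mapping[str, TranscriptModel],
              anchors: Iterable[Anchor], n_bins: int = 50) -> GcMetaplot:
    """Length-scaled GC profile: ``n_bins`` bins start codon -> anchor, then
    ``n_bins`` bins anchor -> stop codon.

    Each segment is cut into equal-width bins (the last absorbs the
    remainder).  An anchor at the CDS start is an error (empty upstream
    segment); anchors whose segments are shorter than ``n_bins`` are
    dropped and tallied.
    """
    acc = np.zeros(2 * n_bins)
    n_used = n_dropped = 0
    for tid, pos in anchors:
        tx = transcripts.get(tid)
        if tx is None:
            n_dropped += 1
            continue
        if not (tx.cds_start < pos < tx.cds_end):
            if pos == tx.cds_start:
                raise ValueError(f"{tid}: anchor at CDS start -> empty upstream segment")
            n_dropped += 1
            continue
        up = _is_gc(tx.sequence[tx.cds_start:pos])
        down = _is_gc(tx.sequence[pos:tx.cds_end])
        if up.size < n_bins or down.size < n_bins:
            n_dropped += 1
            continue
        for seg, off in ((up, 0), (down, n_bins)):
            w = seg.size // n_bins
            for i in range(n_bins):
                chunk = seg[i * w:(i + 1) * w] if i < n_bins - 1 else seg[(n_bins - 1) * w:]
                acc[off + i] += chunk.mean()
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchors for the scaled GC profile")
    return GcMetaplot("scaled", np.arange(2 * n_bins), acc / n_used,
                      n_used, n_dropped)


# ---------------------------------------------------------------------------
# nascent-peptide context
# ---------------------------------------------------------------------------

@dataclass
class PeptideContext:
    aa_freq: pd.DataFrame          # positions (codons rel pause) x amino acids
    charge_profile: pd.Series      # mean residue charge per relative codon
    net_charges: np.ndarray        # per-anchor net charge over the window
    n_anchors: int
    n_dropped: int = 0


def net_charge(peptide: str,
               charge_map: Mapping[str, float] = DEFAULT_CHARGE_MAP) -> float:
    """Net charge of a peptide under the configured residue charge map."""
    return float(sum(charge_map.get(aa, 0.0) for aa in peptide))


def peptide_context(transcripts: Mapping[str, TranscriptModel],
                    anchors: Iterable[Anchor],
                    aa_window: int = 10,
                    charge_map: Mapping[str, float] = DEFAULT_CHARGE_MAP,
                    ) -> PeptideContext:
    """Amino-acid frequencies and charge around the pause codon.

    A nucleotide anchor on any of the 3 bases of a codon marks that codon
    as the pausing codon; translation is in the CDS frame.  The window
    spans ``aa_window`` codons on either side of the pause codon; anchors
    without a complete window (or outside the CDS) are dropped and tallied.
    """
    width = 2 * aa_window + 1
    aa_counts: dict[str, np.ndarray] = {}
    charges = np.zeros(width)
    nets = []
    n_used = n_dropped = 0
    for tid, pos in anchors:
        tx = transcripts.get(tid)
        if tx is None or not (tx.cds_start <= pos < tx.cds_end):
            n_dropped += 1
            continue
        codon = (pos - tx.cds_start) // 3
        ncod = tx.cds_length // 3
        if codon - aa_window < 0 or codon + aa_window >= ncod:
            n_dropped += 1
            continue
        peptide = str(Seq(tx.cds_sequence).translate())
        seg = peptide[codon - aa_window:codon + aa_window + 1]
        for j, aa in enumerate(seg):
            aa_counts.setdefault(aa, np.zeros(width))[j] += 1
            charges[j] += charge_map.get(aa, 0.0)
        nets.append(net_charge(seg, charge_map))
        n_used += 1
    if n_used == 0:
        raise ValueError("no anchor has a complete peptide window")
    positions = np.arange(-aa_window, aa_window + 1)
    freq = pd.DataFrame(
        {aa: v / n_used for aa, v in sorted(aa_counts.items())}, index=positions)
    return PeptideContext(freq, pd.Series(charges / n_used, index=positions),
                          np.array(nets), n_used, n_dropped)


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    transcript_id: str
    start: int          # 0-based
    score: float        # log2 odds (bits)
    p_value: float


@dataclass
class ScoreDistribution:
    """Exact distribution of the lattice score under a 0-order background."""

    scores: np.ndarray       # ascending integer lattice scores
    tail: np.ndarray         # P(score >= scores[i])

    def p_value(self, lattice_score: int) -> float:
        i = np.searchsorted(self.scores, lattice_score, side="left")
        return float(self.tail[i]) if i < self.scores.size else 0.0


def background_composition(transcripts: Iterable[TranscriptModel]) -> np.ndarray:
    """0-order base composition (A, C, G, T) of a transcript set."""
    counts = np.zeros(4)
    for tx in transcripts:
        arr = np.frombuffer(tx.sequence.encode(), dtype=np.uint8)
        for b, i in BASE_INDEX.items():
            counts[i] += int((arr == ord(b)).sum())
    if counts.sum() == 0:
        raise ValueError("empty transcript set")
    return counts / counts.sum()


def score_distribution(ppm: PositionProbabilityMatrix,
                       background: np.ndarray) -> ScoreDistribution:
    """DP over motif columns: exact score distribution under the background.

    Column by column, convolve the current distribution (a map from
    integer lattice score to probability) with the 4 possible base
    contributions weighted by the background.  Exact because scanning and
    the DP share the same integer lattice.
    """
    lattice = ppm.log_odds_lattice(background)
    q = np.asarray(background, dtype=float)
    dist: dict[int, float] = {0: 1.0}
    for j in range(ppm.width):
        nxt: dict[int, float] = {}
        col = lattice[:, j]
        for s, p in dist.items():
            for b in range(4):
                key = s + int(col[b])
                nxt[key] = nxt.get(key, 0.0) + p * q[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = probs[::-1].cumsum()[::-1]
    return ScoreDistribution(scores, tail)


def pwm_scan(ppm: PositionProbabilityMatrix,
             transcript: TranscriptModel,
             background: np.ndarray,
             p_threshold: float = 1e-4,
             dist: ScoreDistribution | None = None) -> list[MotifHit]:
    """Scan one transcript; return hits with exact p <= threshold, by position."""
    if dist is None:
        dist = score_distribution(ppm, background)
    lattice = ppm.log_odds_lattice(background)
    seq = transcript.sequence.upper().replace("U", "T")
    idx = np.full(len(seq), -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    w = ppm.width
    hits: list[MotifHit] = []
    if len(seq) < w:
        return hits
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    cols = np.arange(w)
    scores = np.where(valid, lattice[windows.clip(min=0), cols].sum(axis=1), np.iinfo(np.int64).min)
    for start in np.nonzero(valid)[0]:
        s = int(scores[start])
        p = dist.p_value(s)
        if p <= p_threshold:
            hits.append(MotifHit(transcript.transcript_id, int(start),
                                 s / SCORE_SCALE, p))
    return hits


def motif_pause_association(max_scores: pd.Series,
                            motif_transcripts: Iterable[str]) -> dict:
    """Compare maximum pausing scores of motif-bearing vs motif-free transcripts.

    ``max_scores`` is the per-transcript maximum pausing score (typically
    restricted to paused transcripts); returns group medians, the rank-sum
    statistic and a two-sided p-value.
    """
    from .metrics import compare_groups

    motif_set = set(motif_transcripts)
    with_motif = max_scores[max_scores.index.isin(motif_set)]
    without = max_scores[~max_scores.index.isin(motif_set)]
    if with_motif.empty or without.empty:
        raise ValueError("both motif and non-motif groups must be non-empty")
    stat, p = compare_groups(with_motif.to_numpy(), without.to_numpy())
    return {
        "n_with_motif": int(with_motif.size),
        "n_without_motif": int(without.size),
        "median_with_motif": float(with_motif.median()),
        "median_without_motif": float(without.median()),
        "statistic": stat,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# ensemble free energy
# ---------------------------------------------------------------------------

def ensemble_free_energy(sequence: str) -> float:
    """Partition-function (ensemble) free energy of an RNA, kcal/mol.

    Folds at 37 degC under the standard nearest-neighbor parameter set
    (delegated to the ViennaRNA engine); T is mapped to U.  Fully unpaired
    sequences give 0.0.
    """
    import RNA

    rna = sequence.upper().replace("T", "U")
    fc = RNA.fold_compound(rna)
    _, dg = fc.pf()
    return float(dg)


def mfe_structure(sequence: str) -> tuple[str, float]:
    """Minimum-free-energy structure (dot-bracket) and its energy, kcal/mol."""
    import RNA

    rna = sequence.upper().replace("T", "U")
    fc = RNA.fold_compound(rna)
    structure, mfe = fc.mfe()
    return structure, float(mfe)
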