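"""Footprint diagnostics: length histogram, P-site offsets, periodicity, metagene.

A translating ribosome protects ~27-31 nt of mRNA; its footprints' 5' ends
accumulate a fixed distance (~12-13 nt) upstream of the P-site codon, and,
because elongation proceeds codon by codon, P-sites show 3-nt periodicity
along the CDS.  This module estimates the per-length 5'-end -> P-site
offset from the initiation peak upstream of annotated start codons
(riboWaltz-style), summarizes frame bias, and builds metagene profiles
anchored at the start or stop codon.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_PSITE_OFFSET, RpfAlignment, TranscriptModel

logger = logging.getLogger("ribopause")

#: search window (relative to the start codon) for the 5'-end initiation peak
OFFSET_SEARCH_WINDOW = (-18, -6)
#: peak must exceed this multiple of the window mean to count as real
PEAK_BACKGROUND_RATIO = 2.0


@dataclass
class FrameSummary:
    """Fractions of CDS P-sites in each codon frame; they sum to 1."""

    f0: float
    f1: float
    f2: float
    total: int

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


@dataclass
class MetageneProfile:
    anchor: Literal["start", "stop"]
    positions: np.ndarray          # relative to the anchor codon's first base
    values: np.ndarray             # summed depth per relative position
    n_transcripts: int
    site_mode: Literal["psite", "five_prime"] = "psite"
    normalization: Literal["raw", "per-transcript-mean"] = "raw"


@dataclass
class PsiteOffsets:
    """Estimated per-length offsets with reliability flags."""

    offsets: dict[int, int]
    reliable: dict[int, bool]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length": sorted(self.offsets),
             "offset": [self.offsets[l] for l in sorted(self.offsets)],
             "reliable": [self.reliable[l] for l in sorted(self.offsets)]}
        )


def length_histogram(alignments: Iterable[RpfAlignment]) -> dict[int, int]:
    """Footprint length -> total count (weighted by alignment multiplicity)."""
    hist: Counter[int] = Counter()
    for a in alignments:
        hist[a.length] += a.count
    return dict(sorted(hist.items()))


def estimate_psite_offsets(alignments: Iterable[RpfAlignment],
                           transcripts: Mapping[str, TranscriptModel],
                           lengths: Sequence[int] | None = None,
                           min_reads: int = 200,
                           default: int = DEFAULT_PSITE_OFFSET,
                           ) -> PsiteOffsets:
    """Infer the 5'-end -> P-site offset per footprint length.

    For each length, 5'-end counts are accumulated at positions relative to
    annotated start codons within the search window [-18, -6]; the offset
    is the negated argmax (ties broken toward the smaller offset, i.e. the
    position closer to the start codon).  A length whose peak does not
    exceed twice the window mean, or with fewer than ``min_reads`` reads,
    is flagged unreliable and falls back to the default offset.
    """
    lo, hi = OFFSET_SEARCH_WINDOW
    span = hi - lo + 1
    by_len: dict[int, np.ndarray] = {}
    nreads: Counter[int] = Counter()
    for a in alignments:
        tx = transcripts.get(a.transcript_id)
        if tx is None:
            continue
        rel = a.start5 - tx.cds_start
        nreads[a.length] += a.count
        if lo <= rel <= hi:
            by_len.setdefault(a.length, np.zeros(span, dtype=np.int64))[rel - lo] += a.count

    if lengths is None:
        lengths = sorted(nreads)
    offsets: dict[int, int] = {}
    reliable: dict[int, bool] = {}
    for ln in lengths:
        prof = by_len.get(ln, np.zeros(span, dtype=np.int64))
        ok = nreads[ln] >= min_reads and prof.sum() > 0
        if ok:
            mean = prof.mean()
            peak_idx = int(np.argmax(prof[::-1]))   # reversed: ties -> larger rel
            peak_rel = hi - peak_idx                # => smaller offset
            ok = mean > 0 and prof[peak_rel - lo] >= PEAK_BACKGROUND_RATIO * mean
        if ok:
            offsets[ln] = -peak_rel
            reliable[ln] = True
        else:
            offsets[ln] = default
            reliable[ln] = False
            logger.warning("no reliable 5'-end peak for length %d; default %d used",
                           ln, default)
    return PsiteOffsets(offsets, reliable)


def _psites(alignments: Iterable[RpfAlignment],
            transcripts: Mapping[str, TranscriptModel],
            offsets: Mapping[int, int]):
    for a in alignments:
        tx = transcripts.get(a.transcript_id)
        if tx is None:
            continue
        yield tx, a.start5 + offsets[a.length], a.count


def frame_periodicity(alignments: Iterable[RpfAlignment],
                      transcripts: Mapping[str, TranscriptModel],
                      offsets: Mapping[int, int]) -> FrameSummary:
    """Fractions of offset P-sites in each codon frame, CDS positions only."""
    counts = np.zeros(3, dtype=np.int64)
    for tx, p, c in _psites(alignments, transcripts, offsets):
        if tx.cds_start <= p < tx.cds_end:
            counts[(p - tx.cds_start) % 3] += c
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no CDS P-sites: cannot compute frame periodicity")
    f = counts / total
    return FrameSummary(float(f[0]), float(f[1]), float(f[2]), total)


def metagene_profile(alignments: Iterable[RpfAlignment],
                     transcripts: Mapping[str, TranscriptModel],
                     anchor: Literal["start", "stop"] = "start",
                     window: tuple[int, int] = (-30, 60),
                     offsets: Mapping[int, int] | None = None,
                     site_mode: Literal["psite", "five_prime"] = "psite",
                     normalization: Literal["raw", "per-transcript-mean"] = "raw",
                     ) -> MetageneProfile:
    """Summed site depth at positions relative to the start/stop codon.

    The anchor position is the first base of the start codon or of the stop
    codon.  Transcripts that cannot contain the full window are excluded
    and do not contribute.  ``five_prime`` mode anchors the footprint 5'
    end instead of the offset P-site (offsets then unused).
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window bounds out of order")
    if site_mode == "psite" and offsets is None:
        raise ValueError("psite mode requires offsets")

    values = np.zeros(hi - lo + 1)
    per_tx: dict[str, np.ndarray] = {}
    eligible: set[str] = set()
    for tid, tx in transcripts.items():
        a0 = tx.cds_start if anchor == "start" else tx.cds_end - 3
        if a0 + lo >= 0 and a0 + hi < len(tx):
            eligible.add(tid)

    for a in alignments:
        tx = transcripts.get(a.transcript_id)
        if tx is None or a.transcript_id not in eligible:
            continue
        a0 = tx.cds_start if anchor == "start" else tx.cds_end - 3
        pos = a.start5 + (offsets[a.length] if site_mode == "psite" else 0)
        rel = pos - a0
        if lo <= rel <= hi:
            if normalization == "per-transcript-mean":
                per_tx.setdefault(a.transcript_id, np.zeros(hi - lo + 1))[rel - lo] += a.count
            else:
                values[rel - lo] += a.count

    if normalization == "per-transcript-mean":
        for v in per_tx.values():
            m = v.mean()
            if m > 0:
                values += v / m
    return MetageneProfile(anchor, np.arange(lo, hi + 1), values,
                           len(eligible), site_mode, normalization)
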