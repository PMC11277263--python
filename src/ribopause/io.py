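"""Domain types, coordinate conventions, and file I/O.

Conventions
-----------
All in-memory coordinates are 0-based, half-open.  Everything written to
disk for human consumption (GFF3, report TSVs) is 1-based inclusive; the
alignment TSV keeps 0-based 5' starts (BED-like).  Writers emit UTF-8,
tab-separated text with rows sorted lexicographically by id, so outputs
are byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Mapping

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ribopause")

#: footprint lengths accepted anywhere in the pipeline (library-prep cutoff)
LENGTH_MIN = 23
LENGTH_MAX = 36

#: canonical 5'-end -> P-site offset used when estimation is unavailable
DEFAULT_PSITE_OFFSET = 12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus CDS boundaries in transcript coordinates.

    ``cds_start`` is the 0-based offset of the first CDS base (the A of the
    AUG); ``cds_end`` is the exclusive end, i.e. the position just past the
    stop codon.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    gene_id: str = ""

    def __post_init__(self):
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_end - self.cds_start} "
                "is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start:self.cds_end]


@dataclass(frozen=True)
class RpfAlignment:
    """A ribosome footprint placement in transcript coordinates.

    ``start5`` is the 0-based coordinate of the footprint 5' end; ``count``
    collapses identical placements.
    """

    transcript_id: str
    start5: int
    length: int
    count: int

    def __post_init__(self):
        if self.start5 < 0:
            raise ValueError(f"negative start5 {self.start5}")
        if not (LENGTH_MIN <= self.length <= LENGTH_MAX):
            raise ValueError(
                f"footprint length {self.length} outside [{LENGTH_MIN}, {LENGTH_MAX}]"
            )
        if self.count <= 0:
            raise ValueError(f"non-positive count {self.count}")


@dataclass
class CoverageProfile:
    """Per-base footprint depth along one transcript.

    In ``psite`` mode each footprint contributes ``count`` at its single
    P-site base; in ``body`` mode at every base it covers.
    """

    transcript_id: str
    depth: np.ndarray
    mode: Literal["psite", "body"] = "psite"

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class CountTable:
    """Gene x sample count matrix with an assay tag (``rna`` or ``rpf``)."""

    counts: pd.DataFrame
    assay: Literal["rna", "rpf"] = "rna"

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("duplicate row or column ids")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class AnalysisConfig:
    """Thresholds and geometry shared across the pipeline."""

    psite_offsets: dict[int, int] = field(
        default_factory=lambda: {n: DEFAULT_PSITE_OFFSET for n in range(27, 32)}
    )
    pause_window: int = 1000          # nt, clipped at transcript ends
    pause_score_min: float = 50.0
    pause_z_min: float = 1.65
    pause_depth_min: int = 20
    n_coverage_bins: int = 10
    te_z_threshold: float = 1.5
    de_lfc_min: float = 1.0
    de_p_max: float = 0.05
    rpf_mean_floor: float = 5.0
    coverage_region: Literal["cds", "transcript"] = "cds"
    site_mode: Literal["psite", "five_prime"] = "psite"
    seed: int = 0

    def __post_init__(self):
        w = int(self.pause_window)
        if w < 3:
            raise ValueError("pause_window must be >= 3")
        if w % 2 == 0:          # keep the scoring window symmetric
            w += 1
        self.pause_window = w
        for v in (self.pause_score_min, self.pause_z_min, self.pause_depth_min,
                  self.te_z_threshold, self.de_lfc_min, self.de_p_max):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "psite_offsets" in raw:
            raw["psite_offsets"] = {int(k): int(v) for k, v in raw["psite_offsets"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive (report convention)."""
    return start0 + 1, end0


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# transcriptome I/O (FASTA + GFF3)
# ---------------------------------------------------------------------------

def read_transcriptome(fasta_path: str | Path, gff3_path: str | Path) -> list[TranscriptModel]:
    """Read transcript sequences and their CDS annotation.

    The GFF3 dialect is transcript-space: ``seqid`` is the transcript id and
    CDS features carry 1-based inclusive coordinates along the transcript.
    Transcripts without a CDS are skipped with a warning; a CDS whose length
    is not a multiple of 3 (or that overruns the sequence) fails validation
    and is skipped, with every offending id reported.
    """
    seqs: dict[str, str] = {}
    genes: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    cds_bounds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.seqid
        cds_bounds.setdefault(tid, []).append((feat.start, feat.end))
    for feat in db.features_of_type("mRNA"):
        gid = feat.attributes.get("gene_id", [""])
        genes[feat.seqid] = gid[0] if gid else ""

    models: list[TranscriptModel] = []
    invalid: list[str] = []
    for tid in sorted(seqs):
        if tid not in cds_bounds:
            logger.warning("transcript %s has no CDS feature; skipped", tid)
            continue
        spans = cds_bounds[tid]
        start1 = min(s for s, _ in spans)
        end1 = max(e for _, e in spans)
        start0, end0 = to_zero_based(start1, end1)
        try:
            models.append(TranscriptModel(tid, seqs[tid], start0, end0, genes.get(tid, "")))
        except ValueError as exc:
            invalid.append(tid)
            logger.warning("transcript failed validation: %s", exc)
    if invalid:
        logger.warning("%d transcript(s) rejected: %s", len(invalid), ", ".join(invalid))
    return models


def write_transcriptome(models: Iterable[TranscriptModel],
                        fasta_path: str | Path, gff3_path: str | Path) -> None:
    models = sorted(models, key=lambda m: m.transcript_id)
    records = [SeqRecord(Seq(m.sequence), id=m.transcript_id, description="")
               for m in models]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s1, e1 = to_one_based(0, len(m.sequence))
            fh.write(f"{m.transcript_id}\tribopause\tmRNA\t{s1}\t{e1}\t.\t+\t.\t"
                     f"ID={m.transcript_id};gene_id={m.gene_id}\n")
            cs1, ce1 = to_one_based(m.cds_start, m.cds_end)
            fh.write(f"{m.transcript_id}\tribopause\tCDS\t{cs1}\t{ce1}\t.\t+\t0\t"
                     f"ID=cds:{m.transcript_id};Parent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# alignment I/O (BED-like TSV, 0-based start5)
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ["transcript_id", "start5", "length", "count"]


def read_alignments(tsv_path: str | Path,
                    transcripts: Mapping[str, TranscriptModel] | None = None,
                    ) -> list[RpfAlignment]:
    """Read footprint alignments; optionally validate against transcripts.

    With ``transcripts`` given, records on unknown transcripts or running
    past a transcript end are dropped (tallied in a warning).  Negative
    counts are a hard error in either mode.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV missing columns: {missing}")
    if (df["count"] <= 0).any():
        raise ValueError("alignment TSV contains non-positive counts")

    out: list[RpfAlignment] = []
    dropped = 0
    for row in df.itertuples(index=False):
        if transcripts is not None:
            tx = transcripts.get(row.transcript_id)
            if tx is None or row.start5 < 0 or row.start5 + row.length > len(tx):
                dropped += 1
                continue
        out.append(RpfAlignment(row.transcript_id, int(row.start5),
                                int(row.length), int(row.count)))
    if dropped:
        logger.warning("dropped %d out-of-bounds/unknown alignment record(s)", dropped)
    return out


def write_alignments(alignments: Iterable[RpfAlignment], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.transcript_id, a.start5, a.length, a.count) for a in alignments],
        columns=ALIGNMENT_COLUMNS,
    ).sort_values(ALIGNMENT_COLUMNS, kind="mergesort").reset_index(drop=True)
    df.to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count-table I/O
# ---------------------------------------------------------------------------

def read_counts(tsv_path: str | Path, assay: Literal["rna", "rpf"] = "rna") -> CountTable:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    return CountTable(df, assay=assay)


def write_counts(table: CountTable, tsv_path: str | Path) -> None:
    table.counts.sort_index(kind="mergesort").to_csv(tsv_path, sep="\t")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def build_coverage(alignments: Iterable[RpfAlignment],
                   transcript: TranscriptModel,
                   mode: Literal["psite", "body"] = "psite",
                   offsets: Mapping[int, int] | None = None) -> CoverageProfile:
    """Project footprints on one transcript into a per-base depth vector.

    ``psite`` mode places each footprint's ``count`` at ``start5 +
    offset(length)`` and conserves total mass; ``body`` mode smears the
    count over the whole protected span.  A footprint length without an
    offset is an error naming the length.
    """
    depth = np.zeros(len(transcript), dtype=np.int64)
    for a in alignments:
        if a.transcript_id != transcript.transcript_id:
            continue
        if mode == "psite":
            if offsets is None or a.length not in offsets:
                raise ValueError(f"no P-site offset configured for length {a.length}")
            pos = a.start5 + offsets[a.length]
            if 0 <= pos < len(transcript):
                depth[pos] += a.count
        elif mode == "body":
            depth[a.start5:a.start5 + a.length] += a.count
        else:
            raise ValueError(f"unknown coverage mode {mode!r}")
    return CoverageProfile(transcript.transcript_id, depth, mode=mode)


def build_coverage_all(alignments: Iterable[RpfAlignment],
                       transcripts: Mapping[str, TranscriptModel],
                       mode: Literal["psite", "body"] = "psite",
                       offsets: Mapping[int, int] | None = None,
                       ) -> dict[str, CoverageProfile]:
    """Vectorized multi-transcript version of :func:`build_coverage`."""
    by_tx: dict[str, list[RpfAlignment]] = {tid: [] for tid in transcripts}
    for a in alignments:
        if a.transcript_id in by_tx:
            by_tx[a.transcript_id].append(a)
    profiles: dict[str, CoverageProfile] = {}
    for tid, tx in transcripts.items():
        aligns = by_tx[tid]
        depth = np.zeros(len(tx), dtype=np.int64)
        if aligns:
            if mode == "psite":
                lengths = {a.length for a in aligns}
                missing = lengths - set(offsets or {})
                if missing:
                    raise ValueError(
                        f"no P-site offset configured for length(s) {sorted(missing)}")
                pos = np.array([a.start5 + offsets[a.length] for a in aligns])
                cnt = np.array([a.count for a in aligns])
                ok = (pos >= 0) & (pos < len(tx))
                np.add.at(depth, pos[ok], cnt[ok])
            else:
                for a in aligns:
                    depth[a.start5:a.start5 + a.length] += a.count
        profiles[tid] = CoverageProfile(tid, depth, mode="psite" if mode == "psite" else "body")
    return profiles
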