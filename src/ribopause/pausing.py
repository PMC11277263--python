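"""Ribosome pause detection: sliding-window pause scores, coverage-binned
z-scores, cutoff-based calling, per-transcript maxima over time, clustering.

The pause score of a position is its P-site depth divided by the mean depth
of a symmetric window centered on it (the window includes the position and
is clipped at transcript ends), so uniform coverage scores ~1 and a strong
dwell site scores high.  Scores are standardized within coverage bins --
deciles of the window read total -- so that sparse and deep transcripts are
judged against comparable backgrounds.  A position is called paused when
score, z and depth all strictly exceed their cutoffs (defaults 50, 1.65 and
20 reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .io import AnalysisConfig, CoverageProfile

logger = logging.getLogger("ribopause")


@dataclass
class PauseSite:
    transcript_id: str
    position: int            # 0-based transcript coordinate
    depth: int               # P-site count at the position
    window_mean: float
    window_total: int        # used for coverage binning
    score: float
    z: float = np.nan
    called: bool = False


def pause_scores(coverage: CoverageProfile, window: int = 1000) -> list[PauseSite]:
    """Score every covered position of one transcript.

    For position i the window spans max(0, i-(W-1)/2) .. min(L-1, i+(W-1)/2)
    inclusive; the score is depth[i] over the window mean.  Positions with
    zero depth are not scored.
    """
    if window < 3:
        raise ValueError("window must be >= 3 nt")
    if window % 2 == 0:
        window += 1
    if coverage.mode != "psite":
        raise ValueError("pause scores require P-site coverage")
    depth = coverage.depth
    L = depth.size
    half = (window - 1) // 2
    csum = np.concatenate([[0], np.cumsum(depth)])
    idx = np.nonzero(depth)[0]
    lo = np.maximum(0, idx - half)
    hi = np.minimum(L - 1, idx + half)
    totals = csum[hi + 1] - csum[lo]
    sizes = hi - lo + 1
    means = totals / sizes
    scores = depth[idx] / means
    return [
        PauseSite(coverage.transcript_id, int(i), int(depth[i]),
                  float(m), int(t), float(s))
        for i, m, t, s in zip(idx, means, totals, scores)
    ]


def zscore_by_coverage_bin(sites: Sequence[PauseSite], n_bins: int = 10) -> list[PauseSite]:
    """Fill each site's z-score within its coverage bin.

    Bins are deciles (``n_bins`` quantiles) of the window read totals
    pooled over all sites; within a bin z = (score - mean) / sd.  Singleton
    or zero-variance bins get z = 0 with a warning.
    """
    if not sites:
        return []
    totals = np.array([s.window_total for s in sites], dtype=float)
    scores = np.array([s.score for s in sites])
    if len(sites) < 2 * n_bins:
        bins = np.zeros(len(sites), dtype=int)
    else:
        qs = np.quantile(totals, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(qs, totals, side="left")
    z = np.zeros(len(sites))
    for b in np.unique(bins):
        m = bins == b
        if m.sum() < 2:
            logger.warning("coverage bin %d has a single site; z set to 0", b)
            continue
        sd = scores[m].std(ddof=1)
        if sd == 0:
            logger.warning("coverage bin %d has zero score variance; z set to 0", b)
            continue
        z[m] = (scores[m] - scores[m].mean()) / sd
    for s, zz in zip(sites, z):
        s.z = float(zz)
    return list(sites)


def call_pauses(sites: Iterable[PauseSite],
                score_min: float = 50.0,
                z_min: float = 1.65,
                depth_min: int = 20) -> list[PauseSite]:
    """Apply the strict cutoffs; returns the called subset (flags set in place)."""
    called = []
    for s in sites:
        s.called = (s.score > score_min) and (s.z > z_min) and (s.depth > depth_min)
        if s.called:
            called.append(s)
    return called


def score_timepoint(profiles: Mapping[str, CoverageProfile],
                    config: AnalysisConfig) -> list[PauseSite]:
    """Score, z-standardize (pooled across transcripts) and call one timepoint."""
    sites: list[PauseSite] = []
    for prof in profiles.values():
        sites.extend(pause_scores(prof, config.pause_window))
    zscore_by_coverage_bin(sites, config.n_coverage_bins)
    call_pauses(sites, config.pause_score_min, config.pause_z_min, config.pause_depth_min)
    return sites


def max_pause_per_transcript(sites: Iterable[PauseSite]) -> pd.Series:
    """Maximum pausing score per transcript (0 for transcripts with no score)."""
    best: dict[str, float] = {}
    for s in sites:
        if s.score > best.get(s.transcript_id, 0.0):
            best[s.transcript_id] = s.score
    return pd.Series(best, dtype=float).sort_index()


def pause_matrix(sites_by_timepoint: Mapping[str, Sequence[PauseSite]]) -> pd.DataFrame:
    """Paused-transcripts x timepoints matrix of maximum pausing scores.

    Rows are restricted to transcripts called paused at >= 1 timepoint;
    entries are the maximum score of any position at that timepoint (0 when
    the transcript has no scored position).
    """
    paused: set[str] = set()
    cols: dict[str, pd.Series] = {}
    for tp, sites in sites_by_timepoint.items():
        cols[tp] = max_pause_per_transcript(sites)
        paused.update(s.transcript_id for s in sites if s.called)
    mat = pd.DataFrame(index=sorted(paused), columns=list(sites_by_timepoint))
    for tp, col in cols.items():
        mat[tp] = col.reindex(mat.index).fillna(0.0)
    return mat.astype(float)


def cluster_pause_dynamics(matrix: pd.DataFrame, k: int = 5, seed: int = 0,
                           method: str = "kmeans") -> pd.Series:
    """Cluster per-transcript pause-score time profiles into dynamics classes.

    Rows are z-scored across timepoints before clustering (zero-variance
    rows stay at 0), so classes capture the shape of the dynamics, not the
    magnitude.  Labels are relabeled by descending cluster size; the
    default k = 5 matches the number of dynamics classes distinguished in
    etiolated-seedling light-exposure data.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    n_unique = np.unique(Xz, axis=0).shape[0]
    if n_unique < k:
        logger.warning("only %d distinct profiles for k=%d; reducing k", n_unique, k)
        k = max(1, n_unique)
    if k == 1:
        labels = np.zeros(len(matrix), dtype=int)
    elif method == "kmeans":
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(Xz)
    elif method == "hierarchical-ward":
        labels = fcluster(linkage(Xz, method="ward"), k, criterion="maxclust") - 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # stable relabeling: 0 = largest cluster
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[l] for l in labels], index=matrix.index, name="cluster")


def sites_to_frame(sites: Iterable[PauseSite]) -> pd.DataFrame:
    """Report table (1-based positions) for ``pauses.tsv``."""
    rows = [(s.transcript_id, s.position + 1, s.depth, s.window_mean,
             s.score, s.z, s.called) for s in sites]
    return pd.DataFrame(
        rows, columns=["transcript_id", "position", "depth", "window_mean",
                       "score", "z", "called"],
    ).sort_values(["transcript_id", "position"], kind="mergesort").reset_index(drop=True)
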