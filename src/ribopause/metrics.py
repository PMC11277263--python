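"""Normalization, differential expression/translation, TE, TI, group tests.

Translation efficiency (TE) is the classical footprint-over-mRNA density
ratio; its differential form is standardized robustly across genes and
thresholded at |z| > 1.5.  Translation intensity (TI) is the
coverage-aware statistic TI = median(covered depth) * (covered bases /
region length): a transcript whose footprints pile up at one pause site
has high TE but low TI, which is exactly the regime the statistic was
designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, CoverageProfile, TranscriptModel


# ---------------------------------------------------------------------------
# normalization (median-of-ratios)
# ---------------------------------------------------------------------------

def normalize_counts(table: CountTable) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized table.

    Size factor of a sample = median over genes (positive in all samples)
    of count / geometric mean across samples.
    """
    counts = table.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; consider a pseudocount")
    ref = counts.loc[positive]
    log_gm = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_gm, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors.name = "size_factor"
    return size_factors, counts.div(size_factors, axis=1)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(norm: pd.DataFrame,
                            group_a: Sequence[str],
                            group_b: Sequence[str],
                            test: Literal["nb_wald", "exact_poisson"] = "nb_wald",
                            raw: pd.DataFrame | None = None,
                            assay: Literal["rna", "rpf"] = "rna",
                            lfc_min: float = 1.0,
                            p_max: float = 0.05,
                            rpf_mean_floor: float = 5.0) -> pd.DataFrame:
    """Per-gene log2 fold change B vs A with the dual significance filter.

    log2fc uses group means of normalized counts with pseudocount 0.5.
    ``nb_wald`` fits a per-gene method-of-moments dispersion and tests the
    log fold change by a Wald z; ``exact_poisson`` conditions on the total
    (binomial test on summed counts).  Significance requires |log2fc| >
    lfc_min and p < p_max; the rpf assay additionally requires a mean raw
    count of at least ``rpf_mean_floor`` across the tested samples.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups need at least one sample")
    A = norm[list(group_a)].to_numpy(dtype=float)
    B = norm[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    if test == "nb_wald":
        # pooled method-of-moments dispersion: var = mu + alpha mu^2
        pooled = np.concatenate([A, B], axis=1)
        mu = pooled.mean(axis=1)
        var = pooled.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.clip((var - mu) / np.maximum(mu, 1e-8) ** 2, 0.0, None)
        se2 = lambda m, n: (m + alpha * m ** 2) / np.maximum(n * np.maximum(m, 1e-8) ** 2, 1e-12)
        se_log = np.sqrt(se2(mean_a, A.shape[1]) + se2(mean_b, B.shape[1])) / np.log(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se_log > 0, lfc / se_log, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
    elif test == "exact_poisson":
        ta = A.sum(axis=1)
        tb = B.sum(axis=1)
        na, nb = A.shape[1], B.shape[1]
        p = np.array([
            stats.binomtest(int(round(b)), int(round(a + b)), nb / (na + nb)).pvalue
            if a + b > 0 else 1.0
            for a, b in zip(ta, tb)
        ])
    else:
        raise ValueError(f"unknown test {test!r}")

    sig = (np.abs(lfc) > lfc_min) & (p < p_max)
    if assay == "rpf":
        source = raw if raw is not None else norm
        mean_raw = source[list(group_a) + list(group_b)].mean(axis=1).to_numpy()
        sig &= mean_raw >= rpf_mean_floor
    return pd.DataFrame(
        {"log2fc": lfc, "p_value": p, "significant": sig}, index=norm.index)


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def _tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def translation_efficiency(rpf: CountTable, rna: CountTable,
                           cds_lengths: pd.Series,
                           floor: float = 1.0) -> pd.DataFrame:
    """Per-gene TE per matched sample pair: TPM-like RPF density / RNA density.

    Columns of the two tables are paired in order.  Genes whose mean raw
    count in either assay falls below ``floor`` (or with zero RNA signal)
    are masked to NaN.
    """
    common = rpf.genes.intersection(rna.genes)
    lengths = cds_lengths.reindex(common)
    rpf_t = _tpm(rpf.counts.loc[common], lengths)
    rna_t = _tpm(rna.counts.loc[common], lengths)
    if rpf_t.shape[1] != rna_t.shape[1]:
        raise ValueError("rpf and rna tables must have matched sample columns")
    te = pd.DataFrame(index=common)
    for (rc, rpf_col), (nc, rna_col) in zip(rpf_t.items(), rna_t.items()):
        with np.errstate(divide="ignore", invalid="ignore"):
            te[f"te_{rc}_{nc}"] = np.where(rna_col > 0, rpf_col / rna_col, np.nan)
    low = (rpf.counts.loc[common].mean(axis=1) < floor) | \
          (rna.counts.loc[common].mean(axis=1) < floor)
    te[low] = np.nan
    return te


def delta_te(te_a: pd.Series, te_b: pd.Series, z_threshold: float = 1.5) -> pd.DataFrame:
    """log2 TE change with robust z standardization across genes.

    z = (log2dte - median) / (1.4826 * MAD); a gene is significant when
    |z| strictly exceeds the threshold (default 1.5).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ldte = np.log2(te_b / te_a)
    ldte = pd.Series(ldte, index=te_a.index).replace([np.inf, -np.inf], np.nan)
    med = ldte.median()
    mad = (ldte - med).abs().median()
    scale = 1.4826 * mad if mad > 0 else np.nan
    z = (ldte - med) / scale
    return pd.DataFrame({
        "log2_dte": ldte, "z": z,
        "significant": z.abs() > z_threshold,
    })


# ---------------------------------------------------------------------------
# translation intensity
# ---------------------------------------------------------------------------

@dataclass
class TIResult:
    transcript_id: str
    median_depth: float
    coverage: float        # fraction of region bases covered by footprints
    ti: float
    n_covered: int
    region_length: int


def translation_intensity(coverage: CoverageProfile,
                          transcript: TranscriptModel | None = None,
                          region: Literal["cds", "transcript"] = "cds") -> TIResult:
    """TI = median depth of covered bases x fraction of region covered.

    ``n`` counts region bases with depth > 0; coverage = n / region length;
    the median is over covered bases only (standard median: the two
    central values are averaged when n is even).  TI is 0 iff nothing in
    the region is covered.
    """
    if region == "cds":
        if transcript is None:
            raise ValueError("cds region requires the transcript model")
        depth = coverage.depth[transcript.cds_start:transcript.cds_end]
    else:
        depth = coverage.depth
    if depth.size == 0:
        raise ValueError("empty region")
    covered = depth[depth > 0]
    n = int(covered.size)
    frac = n / depth.size
    median = float(np.median(covered)) if n else 0.0
    return TIResult(coverage.transcript_id, median, frac, median * frac,
                    n, int(depth.size))


# ---------------------------------------------------------------------------
# group comparison (rank sum)
# ---------------------------------------------------------------------------

def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: (U statistic, p).

    Exact distribution for untied samples of size <= 20 per group; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))
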