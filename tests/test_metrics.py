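"""Normalization, DE filters, TE / delta-TE, TI, and rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest

from ribopause import (
    CountTable,
    CoverageProfile,
    TranscriptModel,
    compare_groups,
    delta_te,
    differential_expression,
    normalize_counts,
    translation_efficiency,
    translation_intensity,
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_size_factors_identity_and_scaling():
    df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]},
                      index=["g1", "g2", "g3"])
    sf, norm = normalize_counts(CountTable(df))
    assert sf.tolist() == pytest.approx([1.0, 1.0])

    df2 = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                       index=["g1", "g2", "g3"])
    sf2, norm2 = normalize_counts(CountTable(df2))
    assert sf2["b"] / sf2["a"] == pytest.approx(2.0)
    pd.testing.assert_frame_equal(norm2[["a"]] .rename(columns={"a": "x"}),
                                  norm2[["b"]].rename(columns={"b": "x"}))

    single = pd.DataFrame({"a": [10], "b": [30]}, index=["g1"])
    sf3, _ = normalize_counts(CountTable(single))
    assert sf3["b"] / sf3["a"] == pytest.approx(3.0)

    with pytest.raises(ValueError, match="pseudocount"):
        normalize_counts(CountTable(pd.DataFrame({"a": [0, 5], "b": [5, 0]},
                                                 index=["g1", "g2"])))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _nb(rng, mu, alpha, size):
    n = 1 / alpha
    return rng.negative_binomial(n, n / (n + mu), size=size)


def test_de_identical_groups_not_significant():
    df = pd.DataFrame(np.tile([[100], [200]], (1, 6)),
                      index=["g1", "g2"], columns=[f"s{i}" for i in range(6)])
    res = differential_expression(df.astype(float), df.columns[:3], df.columns[3:])
    assert res["log2fc"].abs().max() == 0
    assert not res["significant"].any()


def test_de_power_on_planted_fold_changes():
    """Planted 4x genes at mean 500, dispersion 0.05, 3 vs 3 are recovered."""
    flagged = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_genes = 100
        mu = np.full((n_genes, 6), 500.0)
        mu[:20, 3:] *= 4
        counts = _nb(rng, mu, 0.05, mu.shape).astype(float)
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(6)])
        _, norm = normalize_counts(CountTable(df.astype(int)))
        res = differential_expression(norm, df.columns[:3], df.columns[3:])
        flagged.append(res["significant"][:20].mean())
    assert np.mean(flagged) >= 0.90


def test_de_rpf_floor_excludes_low_count_genes():
    df = pd.DataFrame({"a1": [1, 500], "a2": [1, 480], "b1": [8, 2000],
                       "b2": [8, 1900]}, index=["low", "high"]).astype(float)
    no_floor = differential_expression(df, ["a1", "a2"], ["b1", "b2"],
                                       test="exact_poisson", raw=df,
                                       assay="rpf", rpf_mean_floor=0.0)
    assert no_floor.loc["low", "significant"]     # passes the dual filter alone
    res = differential_expression(df, ["a1", "a2"], ["b1", "b2"],
                                  test="exact_poisson", raw=df,
                                  assay="rpf", rpf_mean_floor=5.0)
    # "low" has mean raw 4.5 < 5: excluded regardless of its fold change
    assert not res.loc["low", "significant"]


def test_de_null_calibration():
    rng = np.random.default_rng(3)
    n_genes = 2000
    counts = _nb(rng, np.full((n_genes, 6), 200.0), 0.05, (n_genes, 6))
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"s{i}" for i in range(6)])
    _, norm = normalize_counts(CountTable(df))
    res = differential_expression(norm, df.columns[:3], df.columns[3:])
    frac = res["significant"].mean()
    assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_genes)


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def _tables(rpf, rna, genes):
    idx = pd.Index(genes, name="gene_id")
    return (CountTable(pd.DataFrame(rpf, index=idx), "rpf"),
            CountTable(pd.DataFrame(rna, index=idx), "rna"))


def test_te_equal_shares_give_unity():
    rpf, rna = _tables({"s1": [100, 300]}, {"s1": [100, 300]}, ["g1", "g2"])
    lengths = pd.Series({"g1": 300, "g2": 900})
    te = translation_efficiency(rpf, rna, lengths, floor=0)
    assert te.iloc[:, 0].tolist() == pytest.approx([1.0, 1.0])


def test_te_scales_with_rpf_count():
    genes = [f"g{i}" for i in range(1000)]
    rng = np.random.default_rng(0)
    base = rng.integers(50, 500, size=1000)
    rpf_counts = base.copy()
    rpf_counts[0] *= 2     # doubling one gene's RPF count doubles its TE
    rpf, rna = _tables({"s1": rpf_counts}, {"s1": base}, genes)
    lengths = pd.Series(np.full(1000, 600), index=genes)
    te = translation_efficiency(rpf, rna, lengths, floor=0)
    others = te.iloc[1:, 0]
    assert te.iloc[0, 0] / others.median() == pytest.approx(2.0, rel=0.01)


def test_te_zero_rna_masked():
    rpf, rna = _tables({"s1": [10, 10]}, {"s1": [0, 10]}, ["g1", "g2"])
    te = translation_efficiency(rpf, rna, pd.Series({"g1": 300, "g2": 300}),
                                floor=0)
    assert np.isnan(te.iloc[0, 0])


def test_delta_te_robust_z_and_threshold():
    rng = np.random.default_rng(8)
    ldte = rng.normal(0, 0.5, 2000)
    te_a = pd.Series(np.ones(2000), index=range(2000))
    te_b = pd.Series(2.0 ** ldte, index=range(2000))
    res = delta_te(te_a, te_b)
    # gene at the cohort median -> z ~ 0
    med_gene = (res["log2_dte"] - res["log2_dte"].median()).abs().idxmin()
    assert abs(res.loc[med_gene, "z"]) < 0.01
    # symmetric null: ~13.4 % beyond |z| > 1.5 (2 * normal tail)
    frac = res["significant"].mean()
    assert abs(frac - 2 * 0.0668) < 0.03
    # strict threshold: |z| exactly 1.5 is not significant
    assert not (pd.Series([1.5]).abs() > 1.5).iloc[0]


# ---------------------------------------------------------------------------
# translation intensity
# ---------------------------------------------------------------------------

def _ti(depths, region_len):
    """TI over a whole transcript of length ``region_len``."""
    tx = TranscriptModel("t", "A" * region_len, 0, region_len - region_len % 3)
    depth = np.zeros(region_len, dtype=int)
    depth[:len(depths)] = depths
    return translation_intensity(CoverageProfile("t", depth), tx, "transcript")


def test_ti_hand_examples():
    r = _ti([10] * 9, 9)          # uniform full coverage
    assert (r.median_depth, r.coverage, r.ti) == (10, 1.0, 10)

    r = _ti([5, 5, 5, 5], 8)      # half the region covered at depth 5
    assert r.median_depth == 5 and r.coverage == 0.5 and r.ti == 2.5

    r = _ti([2, 4, 6, 8], 8)      # even n: average the two central values
    assert r.median_depth == 5 and r.ti == 2.5

    with pytest.raises(ValueError, match="empty region"):
        tx = TranscriptModel("t", "A" * 9, 0, 9)
        translation_intensity(CoverageProfile("t", np.array([], dtype=int)),
                              tx, region="transcript")


def test_ti_matches_sort_based_oracle_and_invariants():
    rng = np.random.default_rng(17)
    for _ in range(500):
        L = int(rng.integers(6, 120))
        depth = rng.poisson(rng.uniform(0.1, 4.0), L)
        r = _ti(depth, L)
        covered = sorted(d for d in depth[:r.region_length] if d > 0)
        n = len(covered)
        if n == 0:
            assert r.ti == 0
            continue
        oracle = (covered[n // 2] if n % 2 == 1
                  else (covered[n // 2 - 1] + covered[n // 2]) / 2)
        assert r.median_depth == oracle
        assert 0 <= r.coverage <= 1
        assert r.ti <= r.median_depth
        assert r.ti == pytest.approx(oracle * n / r.region_length)


def test_ti_permutation_invariant():
    depth = np.array([0, 3, 9, 0, 1, 7, 0, 2, 5], dtype=int)
    tx = TranscriptModel("t", "A" * 9, 0, 9)
    r1 = translation_intensity(CoverageProfile("t", depth), tx)
    rng = np.random.default_rng(0)
    r2 = translation_intensity(CoverageProfile("t", rng.permutation(depth)), tx)
    assert r1.ti == r2.ti


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def test_compare_groups_examples():
    assert compare_groups([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)
    assert compare_groups([1, 2, 3], [4, 5, 6])[1] == pytest.approx(0.1)
    with pytest.raises(ValueError):
        compare_groups([], [1.0])
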