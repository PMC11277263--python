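"""Logos, GC metaplots, peptide context, PWM scanning, free energy."""

import numpy as np
import pandas as pd
import pytest

from ribopause import (
    SimulationConfig,
    TranscriptModel,
    background_composition,
    cgc_motif_ppm,
    context_logo,
    ensemble_free_energy,
    gc_absolute,
    gc_scaled,
    generate_transcriptome,
    mfe_structure,
    motif_pause_association,
    net_charge,
    peptide_context,
    pwm_from_sequences,
    pwm_scan,
    read_ppm,
    score_distribution,
    write_ppm,
)
from ribopause.seqfeatures import BASE_INDEX, SCORE_SCALE


def _tx(seq, cds_start=0, cds_end=None, tid="t1"):
    cds_end = cds_end if cds_end is not None else len(seq) - len(seq) % 3
    return TranscriptModel(tid, seq, cds_start, cds_end)


# ---------------------------------------------------------------------------
# context logo
# ---------------------------------------------------------------------------

def test_logo_pure_c_column():
    seq = "A" * 30 + "C" + "A" * 40 + "GGG"
    tx = _tx(seq, 0, 72)
    logo = context_logo({"t1": tx}, [("t1", 43)], window=(-30, 10))
    col = np.where(logo.positions == -13)[0][0]
    assert logo.probs[BASE_INDEX["C"], col] == 1.0
    assert np.allclose(logo.probs.sum(axis=0), 1.0)


def test_logo_uniform_background_and_planted_recovery():
    cfg = SimulationConfig(n_transcripts=700, seed=19, paused_fraction=1.0,
                           c13_prob=0.6, plant_motif=False, gc_offset_paused=0.0,
                           gc_slope=0.0)
    models, truth = generate_transcriptome(cfg)
    txs = {m.transcript_id: m for m in models}
    anchors = [(tid, int(r["pause_pos"])) for tid, r in truth.iterrows()]
    logo = context_logo(txs, anchors)
    col13 = np.where(logo.positions == -13)[0][0]
    c13 = logo.probs[BASE_INDEX["C"], col13]
    # planted 60 % C at -13, on a 25 % background: 0.6 + 0.4 * 0.25 = 0.70
    assert abs(c13 - 0.70) < 0.03
    # unplanted positions stay at background
    far = np.where(logo.positions == -25)[0][0]
    assert abs(logo.probs[:, far] - 0.25).max() < 0.04


def test_logo_drops_incomplete_windows():
    tx = _tx("ATG" * 20, 0, 60)
    logo = context_logo({"t1": tx}, [("t1", 2), ("t1", 35)], window=(-30, 10))
    assert logo.n_sequences == 1
    with pytest.raises(ValueError):
        context_logo({"t1": tx}, [("t1", 2)], window=(-30, 30))


# ---------------------------------------------------------------------------
# GC metaplots
# ---------------------------------------------------------------------------

def test_gc_absolute_pure_sequences():
    gc_tx = _tx("G" * 99, 0, 99)
    at_tx = _tx("A" * 99, 0, 99, tid="t2")
    plot = gc_absolute({"t1": gc_tx}, [("t1", 49)], flank=20)
    assert (plot.values == 1.0).all()
    plot2 = gc_absolute({"t2": at_tx}, [("t2", 49)], flank=20)
    assert (plot2.values == 0.0).all()


def test_gc_scaled_flat_ramp_and_errors():
    flat = _tx("GCGCGC" * 40, 0, 240)
    plot = gc_scaled({"t1": flat}, [("t1", 120)])
    assert plot.values == pytest.approx(np.ones(100))

    # a 0.3 -> 0.7 GC ramp yields increasing bin means
    rng = np.random.default_rng(0)
    L = 3000
    p = np.linspace(0.3, 0.7, L)
    bases = np.where(rng.random(L) < p, "G", "A")
    ramp = _tx("".join(bases), 0, 3000, tid="t3")
    plot3 = gc_scaled({"t3": ramp}, [("t3", 1500)])
    first, last = plot3.values[:20].mean(), plot3.values[-20:].mean()
    assert last - first > 0.2

    with pytest.raises(ValueError, match="empty upstream"):
        gc_scaled({"t1": flat}, [("t1", 0)])


# ---------------------------------------------------------------------------
# peptide context
# ---------------------------------------------------------------------------

def test_net_charge_examples():
    assert net_charge("KK") == 2.0      # AAA AAA
    assert net_charge("DE") == -2.0     # GAT GAA
    assert net_charge("HHH") == 0.0


def test_peptide_context_codon_mapping():
    # CDS: M K K D E * ; anchor on any base of codon 2 marks lysine
    cds = "ATG" + "AAA" + "AAG" + "GAT" + "GAA" + "TAA"
    tx = _tx("GGGGGG" + cds + "GGGGGG", 6, 6 + len(cds))
    for off in (0, 1, 2):
        ctx = peptide_context({"t1": tx}, [("t1", 6 + 6 + off)], aa_window=1)
        assert ctx.aa_freq.loc[0, "K"] == 1.0
    ctx = peptide_context({"t1": tx}, [("t1", 6 + 9)], aa_window=1)   # codon D
    assert ctx.net_charges[0] == pytest.approx(-1.0)   # K, D, E window: +1-1-1


# ---------------------------------------------------------------------------
# PWM scanning and exact p-values
# ---------------------------------------------------------------------------

def test_consensus_scores_maximum():
    ppm = pwm_from_sequences(["CGCCGC", "CGCCGC", "CGCAGC"], pseudocount=0.5)
    bg = np.full(4, 0.25)
    lattice = ppm.log_odds_lattice(bg)
    cons = ppm.consensus()
    cons_score = sum(lattice[BASE_INDEX[b], j] for j, b in enumerate(cons))
    assert cons_score == lattice.max(axis=0).sum()


def test_pvalue_dp_equals_exhaustive_enumeration():
    """Exact DP tail matches brute-force enumeration over all 4^6 words."""
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 30, size=(4, 6)).astype(float)
    ppm_probs = counts / counts.sum(axis=0)
    from ribopause.seqfeatures import PositionProbabilityMatrix
    ppm = PositionProbabilityMatrix(ppm_probs, np.arange(1, 7))
    bg = np.array([0.3, 0.2, 0.3, 0.2])
    dist = score_distribution(ppm, bg)
    lattice = ppm.log_odds_lattice(bg)

    words = {}
    for w in range(4 ** 6):
        digits = [(w // 4 ** j) % 4 for j in range(6)]
        s = int(sum(lattice[d, j] for j, d in enumerate(digits)))
        p = float(np.prod([bg[d] for d in digits]))
        words[s] = words.get(s, 0.0) + p
    scores = np.array(sorted(words))
    tails = np.cumsum([words[s] for s in scores][::-1])[::-1]
    assert np.array_equal(dist.scores, scores)
    np.testing.assert_allclose(dist.tail, tails, atol=1e-12)
    for s, t in zip(scores, tails):
        assert dist.p_value(int(s)) == pytest.approx(t, abs=1e-12)


def test_scan_finds_planted_motif():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, 300))
    motif = "CGCCGCCGCCGCCGCC"
    seq[100:116] = list(motif)
    tx = _tx("".join(seq), 0, 300)
    ppm = cgc_motif_ppm()
    bg = np.full(4, 0.25)
    hits = pwm_scan(ppm, tx, bg, p_threshold=1e-4)
    assert any(h.start == 100 for h in hits)
    top = max(hits, key=lambda h: h.score)
    assert top.start == 100
    assert hits == sorted(hits, key=lambda h: h.start)


def test_ppm_file_roundtrip(tmp_path):
    ppm = cgc_motif_ppm()
    assert ppm.consensus() == "CGCCGCCGCCGCCGCC"
    path = tmp_path / "m.ppm"
    write_ppm(ppm, path)
    back = read_ppm(path)
    np.testing.assert_allclose(back.probs, ppm.probs, atol=1e-6)
    assert back.n_sequences == ppm.n_sequences


def test_motif_pause_association_power_and_errors():
    rng = np.random.default_rng(23)
    with_motif = pd.Series(rng.normal(200, 30, 50),
                           index=[f"m{i}" for i in range(50)])
    without = pd.Series(rng.normal(80, 30, 50),
                        index=[f"n{i}" for i in range(50)])
    res = motif_pause_association(pd.concat([with_motif, without]),
                                  with_motif.index)
    assert res["p_value"] < 1e-3
    assert res["median_with_motif"] > res["median_without_motif"]
    with pytest.raises(ValueError):
        motif_pause_association(without, set())


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def test_ensemble_free_energy_examples():
    assert ensemble_free_energy("AAAAAAAAAA") == pytest.approx(0.0, abs=1e-9)
    dg = ensemble_free_energy("CGCCGCCGCCGCCGCC")
    assert dg == pytest.approx(-2.95, abs=0.05)
    # T and U spellings are equivalent
    assert ensemble_free_energy("GGGAAATCCC") == ensemble_free_energy("GGGAAAUCCC")
    struct, mfe = mfe_structure("CGCCGCCGCCGCCGCC")
    assert "(" in struct and mfe < 0
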