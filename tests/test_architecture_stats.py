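"""Feature extraction, PWM splice-site scoring, and association statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicearch.archstats import (
    association_matrix,
    build_pwm,
    build_splice_site_model,
    extract_features_es,
    extract_features_ir,
    fisher_3n,
    gc_content,
    score_site,
    signed_ks,
    spearman_assoc,
    spliceosome_rank_score,
    splice_site_windows,
)
from splicearch.genemodel import GeneModel
from splicearch.synthetic import GenomeSpec, generate_genome


# ---------------------------------------------------------------------------
# features


def test_hand_built_gene_features_match_manual_arithmetic(small_synth):
    syn = small_synth
    ss = build_splice_site_model(syn.models, syn.genome)
    feats = extract_features_es(syn.models, syn.genome, ss)
    # verify one event against hand computation
    gid = feats.iloc[0]["gene_id"]
    m = syn.models[gid]
    row = feats[(feats.gene_id == gid) & (feats.exon_index == 1)].iloc[0]
    ex, intr = m.exon_lengths(), m.intron_lengths()
    assert row.cds_length == sum(ex)
    assert row.gene_length == sum(ex) + sum(intr)
    assert row.introns_per_gene == len(intr)
    assert row.exon_length == ex[1]
    assert row.upstream_intron_length == intr[0]
    assert row.downstream_intron_length == intr[1]
    assert row.event_position == ex[0] + intr[0]
    assert row.local_intron_exon_ratio == pytest.approx((intr[0] + intr[1]) / (2 * ex[1]))
    assert row.total_intron_exon_ratio == pytest.approx(sum(intr) / sum(ex))
    assert bool(row.is_3n) == (ex[1] % 3 == 0)
    e_seq = m.exon_seqs(syn.genome)[1]
    assert row.gc_ex == pytest.approx(gc_content(e_seq))
    i_seqs = m.intron_seqs(syn.genome)
    assert row.gc_in == pytest.approx((gc_content(i_seqs[0]) + gc_content(i_seqs[1])) / 2)
    assert row.dgc_in_ex == pytest.approx(row.gc_in - row.gc_ex)


def test_3n_flag_and_zero_dgc():
    assert (99 % 3 == 0) is True
    row_gc = gc_content("GGCC"), gc_content("GCGC")
    assert row_gc[0] == row_gc[1]  # identical GC -> dGC would be 0


def test_ir_features_use_flanking_exon_mean_gc(small_synth):
    syn = small_synth
    ss = build_splice_site_model(syn.models, syn.genome)
    feats = extract_features_ir(syn.models, syn.genome, ss)
    row = feats.iloc[0]
    m = syn.models[row.gene_id]
    i = int(row.intron_index)
    exs = m.exon_seqs(syn.genome)
    assert row.gc_ex == pytest.approx((gc_content(exs[i]) + gc_content(exs[i + 1])) / 2)
    assert row.intron_length == m.intron_lengths()[i]


# ---------------------------------------------------------------------------
# PWM scoring


def test_identical_training_sites_score_zero():
    sites = ["CAGGTAAGT"] * 25
    pwm = build_pwm(sites)
    assert score_site("CAGGTAAGT", pwm) == pytest.approx(0.0, abs=1e-9)
    assert score_site("AAGGTAAGT", pwm) > 0.5


def test_single_position_deficit_is_frequency_difference():
    # one variable position: A 70% / G 30%; all others fixed
    sites = ["A" + "C" * 8] * 7 + ["G" + "C" * 8] * 3
    pwm = build_pwm(sites, pseudo=0.0)
    d_a = score_site("A" + "C" * 8, pwm)
    d_g = score_site("G" + "C" * 8, pwm)
    assert d_a == pytest.approx(0.0)
    assert d_g == pytest.approx(0.4)  # 0.7 - 0.3


def test_window_length_contracts():
    pwm5 = build_pwm(["CAGGTAAGT"] * 3)
    with pytest.raises(ValueError):
        score_site("CAGGTAAGTA", pwm5)  # 10-mer vs 9-bp model
    with pytest.raises(ValueError):
        build_pwm(["ACGT", "ACG"])


def test_n_positions_skipped_in_scoring():
    sites = ["CAGGTAAGT"] * 10
    pwm = build_pwm(sites)
    assert score_site("NAGGTAAGT", pwm) == pytest.approx(0.0, abs=1e-9)


def test_adding_consensus_sharpens_the_model():
    # reinforcing the consensus never *decreases* a non-consensus site's
    # distance (each mismatched position's deficit grows by (n-A)/(n(n+1)))
    # and the consensus itself keeps distance 0
    rng = np.random.default_rng(0)
    sites = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(50)]
    pwm = build_pwm(sites, pseudo=0.0)
    consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=0))
    pwm2 = build_pwm(sites + [consensus], pseudo=0.0)
    assert score_site(consensus, pwm2) == pytest.approx(0.0, abs=1e-9)
    for s in sites:
        assert score_site(s, pwm2) >= score_site(s, pwm) - 1e-9


def test_splice_site_windows_have_canonical_geometry(small_synth):
    syn = small_synth
    for m in syn.models.values():
        for _, w5, w3 in splice_site_windows(m, syn.genome):
            assert len(w5) == 9 and len(w3) == 23
    # low-noise genome: consensus distance of real sites is small on average
    ss = build_splice_site_model(syn.models, syn.genome)
    d5 = [score_site(w5, ss.pwm5) for m in syn.models.values() for _, w5, _ in splice_site_windows(m, syn.genome)]
    assert np.mean(d5) < 1.5


# ---------------------------------------------------------------------------
# association statistics


def test_signed_ks_identical_samples_is_na():
    rng = np.random.default_rng(1)
    x = rng.normal(size=400)
    res = signed_ks(x, x)
    assert res.sign == 0 and math.isnan(res.d_signed)


def test_signed_ks_detects_planted_shift_direction():
    rng = np.random.default_rng(2)
    neg = rng.normal(0, 1, 500)
    pos = neg + 0.5
    up = signed_ks(pos, neg)
    assert up.sign == 1 and up.d_signed > 0 and up.p_greater < 0.01
    down = signed_ks(neg - 0.5, neg)
    assert down.sign == -1 and down.d_signed < 0
    assert abs(up.d_signed) <= 1.0


def test_signed_ks_rejects_empty_sample():
    with pytest.raises(ValueError):
        signed_ks([], [1.0, 2.0])


def test_fisher_3n_balanced_table_is_null():
    res = fisher_3n(50, 50, 50, 50)
    assert res["odds_ratio"] == pytest.approx(1.0)
    assert res["p"] == pytest.approx(1.0)
    assert res["sign"] == 0


def test_fisher_3n_strong_enrichment_detected():
    # the frame-preservation contrast printed for the ctenophore dataset:
    # 76.9% 3n among positives vs 37.8% among negatives
    res = fisher_3n(77, 23, 378, 622)
    assert res["sign"] == 1
    assert res["p"] < 1e-10


def test_fisher_3n_matches_hypergeometric_enumeration_oracle():
    # exact tail enumeration for small-margin tables
    rng = np.random.default_rng(3)
    for _ in range(20):
        a, b, c, d = rng.integers(0, 15, 4)
        res = fisher_3n(int(a), int(b), int(c), int(d))
        # oracle: sum hypergeometric pmf over tables as or more extreme
        n1, n2 = a + b, c + d
        k = a + c
        N = n1 + n2
        pmf = stats.hypergeom(N, n1, k).pmf
        p0 = pmf(a)
        p = sum(pmf(x) for x in range(max(0, k - n2), min(k, n1) + 1) if pmf(x) <= p0 + 1e-12)
        assert res["p"] == pytest.approx(p, abs=1e-8)


def test_fisher_3n_degenerate_rows_still_defined():
    res = fisher_3n(0, 0, 10, 5)
    assert 0.0 <= res["p"] <= 1.0


def test_spearman_perfect_monotone():
    x = np.arange(50.0)
    assert spearman_assoc(x, x)["rho"] == pytest.approx(1.0)
    assert spearman_assoc(x, -x)["rho"] == pytest.approx(-1.0)


def test_spearman_recovers_noisy_trend_sign():
    rng = np.random.default_rng(4)
    x = np.arange(200.0)
    y = x + rng.normal(0, 50, 200)
    res = spearman_assoc(x, y)
    assert res["rho"] > 0 and res["significant"]


def test_association_matrix_shapes(small_synth):
    syn = small_synth
    ss = build_splice_site_model(syn.models, syn.genome)
    feats = extract_features_es(syn.models, syn.genome, ss)
    half = len(feats) // 2
    cols = ["exon_length", "upstream_intron_length", "gene_length"]
    mat = association_matrix(feats.iloc[:half], feats.iloc[half:], cols)
    assert list(mat["feature"]) == cols
    assert set(mat["sign"]).issubset({-1, 0, 1})


# ---------------------------------------------------------------------------
# spliceosome rank score


def test_rank_score_exchangeable_expression_near_midrank():
    rng = np.random.default_rng(5)
    expr = pd.Series(rng.lognormal(0, 1, 5000), index=[f"g{i}" for i in range(5000)])
    # a fixed 82-gene panel carries quantile noise of sd ~ 199/sqrt(12*82);
    # average over several independent panels to test the 100.5 expectation
    scores = []
    for k in range(6):
        splice = [f"g{i}" for i in rng.choice(5000, 82, replace=False)]
        scores.append(spliceosome_rank_score(expr, splice, n_subsets=150, seed=6 + k))
    se = 199.0 / math.sqrt(12 * 82) / math.sqrt(len(scores))
    assert abs(np.mean(scores) - 100.5) < 3 * se + 1.0


def test_rank_score_dominant_spliceosome_saturates():
    rng = np.random.default_rng(7)
    expr = pd.Series(rng.lognormal(0, 1, 3000), index=[f"g{i}" for i in range(3000)])
    splice = [f"s{i}" for i in range(82)]
    expr = pd.concat([expr, pd.Series(1e9 + np.arange(82.0), index=splice)])
    score = spliceosome_rank_score(expr, splice, n_subsets=100, seed=8)
    # subsets occasionally contain other spliceosomal genes (~5 of 199 here),
    # so the score approaches 200 minus half the expected co-occupancy
    assert score > 195.0


def test_rank_score_seed_determinism():
    rng = np.random.default_rng(9)
    expr = pd.Series(rng.lognormal(0, 1, 1000), index=[f"g{i}" for i in range(1000)])
    splice = [f"g{i}" for i in range(40)]
    a = spliceosome_rank_score(expr, splice, n_subsets=50, seed=10)
    b = spliceosome_rank_score(expr, splice, n_subsets=50, seed=10)
    assert a == b
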