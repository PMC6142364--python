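"""Logistic ES classifier, ROC/threshold, I_ES grid, PIC, unit conversion."""

import math
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicearch.predictor import (
    COUPLED_BETA,
    SimGenomeParams,
    balance_classes,
    compute_ies,
    density_units_convert,
    grid_axes,
    ies_grid_sweep,
    pic_ancestral,
    pic_root_estimate,
    plant_es_labels,
    real_vs_simulated_ies,
    roc_and_threshold,
    simulate_architectures,
    train_es_classifier,
    true_model_scores,
)


@pytest.fixture(scope="module")
def coupled_data():
    feats = simulate_architectures(
        SimGenomeParams(4.0, 500.0, n_genes=8000), n_exons=14000, seed=21
    )
    y = plant_es_labels(feats, seed=22)
    return balance_classes(feats, y, seed=23)


@pytest.fixture(scope="module")
def fitted_model(coupled_data):
    X, y = coupled_data
    return train_es_classifier(X, y, seed=24)


# ---------------------------------------------------------------------------
# simulated architectures


def test_architecture_sample_means_match_parameters():
    p = SimGenomeParams(15.0, 2000.0, n_genes=2000)
    feats = simulate_architectures(p, n_exons=10_000, seed=1)
    up = feats["upstream_intron_length"].to_numpy(dtype=float)
    se = up.std(ddof=1) / np.sqrt(len(up))
    assert abs(up.mean() - 2000.0) < 3 * se + 2  # +2 for integer rounding/floors


def test_higher_density_shrinks_exons():
    lo = simulate_architectures(SimGenomeParams(3.0, 500.0, n_genes=2000), seed=2)
    hi = simulate_architectures(SimGenomeParams(12.0, 500.0, n_genes=2000), seed=2)
    assert hi["exon_length"].mean() < lo["exon_length"].mean() / 2


def test_low_density_returns_fewer_than_requested_exons():
    feats = simulate_architectures(
        SimGenomeParams(0.5, 300.0, n_genes=20_000), n_exons=10_000, seed=3
    )
    assert 0 < len(feats) < 10_000


def test_invalid_sim_params():
    with pytest.raises(ValueError):
        SimGenomeParams(-1.0, 100.0)
    with pytest.raises(ValueError):
        SimGenomeParams(1.0, 0.0)


# ---------------------------------------------------------------------------
# classifier


def test_planted_coefficients_recovered_within_cis(coupled_data):
    X, y = coupled_data
    model = train_es_classifier(X, y, seed=5)
    ci = model.conf_int()
    names = [c for c in model.params.index]
    covered = sum(
        1 for c in names if ci.loc[c, "lower"] <= COUPLED_BETA[c] <= ci.loc[c, "upper"]
    )
    assert covered >= len(names) - 2
    # strongest planted effects keep their sign
    assert model.params["exon_length"] < 0
    assert model.params["upstream_intron_length"] > 0


def test_null_labels_give_chance_auroc():
    feats = simulate_architectures(SimGenomeParams(4.0, 400.0, n_genes=3000), seed=6)
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, len(feats))
    model = train_es_classifier(feats, y, seed=8)
    assert abs(model.auroc - 0.5) < 0.05


def test_separable_feature_gives_perfect_auroc_and_midgap_threshold():
    rng = np.random.default_rng(9)
    n = 400
    scores = np.concatenate([rng.uniform(0.0, 0.3, n), rng.uniform(0.7, 1.0, n)])
    labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    roc = roc_and_threshold(scores, labels)
    assert roc.auroc == pytest.approx(1.0)
    assert roc.sensitivity + roc.specificity == pytest.approx(2.0)
    assert 0.3 <= roc.threshold <= 1.0  # sits between the clusters


def test_random_scorer_auroc_ci_covers_half():
    rng = np.random.default_rng(10)
    scores = rng.random(2000)
    labels = rng.integers(0, 2, 2000)
    roc = roc_and_threshold(scores, labels)
    assert roc.auroc_ci[0] - 0.03 <= 0.5 <= roc.auroc_ci[1] + 0.03


def test_step_roc_selects_dominant_point():
    scores = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.55])
    labels = np.array([1, 1, 1, 0, 0, 0, 1])
    roc = roc_and_threshold(scores, labels)
    # exhaustive scan oracle over candidate thresholds
    best = max(
        ((np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t), t)
         for t in np.unique(scores)),
    )
    got = np.mean(scores[labels == 1] >= roc.threshold) + np.mean(
        scores[labels == 0] < roc.threshold
    )
    assert got == pytest.approx(best[0])


def test_held_out_auroc_close_to_oracle(coupled_data, fitted_model):
    X, y = coupled_data
    # theoretical AUROC of the true model, by large-sample oracle simulation
    big = simulate_architectures(SimGenomeParams(4.0, 500.0, n_genes=20_000), n_exons=60_000, seed=30)
    yb = plant_es_labels(big, seed=31)
    sb = true_model_scores(big)
    pos, neg = sb[yb == 1], sb[yb == 0]
    rng = np.random.default_rng(32)
    theo = float(
        np.mean(rng.choice(pos, 200_000) > rng.choice(neg, 200_000))
    )
    assert abs(fitted_model.auroc - theo) < 0.02


def test_model_json_roundtrip(tmp_path, fitted_model, coupled_data):
    X, _ = coupled_data
    p = tmp_path / "model.json"
    fitted_model.to_json(p)
    from splicearch.predictor import EsModel

    back = EsModel.from_json(p)
    np.testing.assert_allclose(
        back.predict_proba(X.head(50)), fitted_model.predict_proba(X.head(50))
    )
    assert back.threshold == fitted_model.threshold


# ---------------------------------------------------------------------------
# I_ES and the grid


def test_compute_ies_counts_above_threshold(fitted_model, coupled_data):
    X, _ = coupled_data
    assert compute_ies(X, fitted_model, threshold=-1.0) == 1.0
    assert compute_ies(X, fitted_model, threshold=2.0) == 0.0
    scores = fitted_model.predict_proba(X)
    med = float(np.median(scores))
    assert compute_ies(X, fitted_model, threshold=med) == pytest.approx(0.5, abs=0.02)


def test_grid_axes_cardinality_and_cubic_spacing():
    d, l = grid_axes()
    assert len(d) == 40 and len(l) == 40 and len(d) * len(l) == 1600
    assert d[0] == 0.5 and d[-1] == 15.0
    assert l[0] == 10.0 and l[-1] == 8000.0
    steps = np.diff(l)
    assert (np.diff(steps) > 0).all()  # cubic spacing densifies short lengths
    assert np.allclose(np.diff(d), np.diff(d)[0])  # density axis regular


def test_grid_sweep_monotone_and_deterministic(fitted_model):
    g1 = ies_grid_sweep(fitted_model, 6, 6, n_genes=1200, n_exons=700, seed=40)
    g2 = ies_grid_sweep(fitted_model, 6, 6, n_genes=1200, n_exons=700, seed=40)
    pd.testing.assert_frame_equal(g1, g2)
    assert len(g1) == 36
    rho_len = stats.spearmanr(g1["intron_len_mean"], g1["ies"])
    assert rho_len.statistic > 0 and rho_len.pvalue < 0.01


def test_real_vs_simulated_pairing(fitted_model):
    grid = ies_grid_sweep(fitted_model, 8, 8, n_genes=2500, n_exons=1500, seed=41)
    # "real" genomes = architecture-coupled synthetic genomes spanning the grid
    rows = []
    rng = np.random.default_rng(42)
    for k in range(15):
        d = float(rng.uniform(1.5, 14.0))
        L = float(rng.uniform(50, 7000))
        feats = simulate_architectures(SimGenomeParams(d, L, n_genes=2500), n_exons=1500,
                                       seed=43 + k)
        rows.append((k, d, L, compute_ies(feats, fitted_model)))
    real = pd.DataFrame(rows, columns=["genome_id", "intron_density", "intron_len_mean", "ies"])
    paired, fit = real_vs_simulated_ies(real, grid)
    assert len(paired) == 15
    assert fit["slope"] > 0
    assert fit["r_squared"] > 0.9


def test_out_of_range_genome_clamped(fitted_model):
    grid = ies_grid_sweep(fitted_model, 4, 4, n_genes=600, n_exons=300, seed=44)
    real = pd.DataFrame(
        [(0, 30.0, 20000.0, 0.9)],
        columns=["genome_id", "intron_density", "intron_len_mean", "ies"],
    )
    with pytest.warns(UserWarning, match="clamped"):
        paired, _ = real_vs_simulated_ies(real, grid)
    assert paired.iloc[0]["cell_density"] == grid["intron_density"].max()


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts


def test_pic_two_tip_closed_form():
    est = pic_root_estimate("(a:2.0,b:1.0);", {"a": 10.0, "b": 4.0})
    assert est == pytest.approx((10 / 2 + 4 / 1) / (1 / 2 + 1 / 1))


def test_pic_symmetric_tree_root_is_tip_mean():
    newick = "((a:1,b:1):1,(c:1,d:1):1);"
    vals = {"a": 2.0, "b": 4.0, "c": 6.0, "d": 8.0}
    assert pic_root_estimate(newick, vals) == pytest.approx(np.mean(list(vals.values())))


def _oracle_pic(tree_dict, bl, vals):
    """Brute-force recursive weighted averaging on a nested-dict tree."""

    def rec(node):
        if isinstance(node, str):
            return vals[node], bl[node]
        (c1, c2) = node
        x1, l1 = rec(c1)
        x2, l2 = rec(c2)
        v = (x1 / l1 + x2 / l2) / (1 / l1 + 1 / l2)
        return v, bl[node] + l1 * l2 / (l1 + l2)

    return rec(tree_dict)[0]


def test_pic_matches_recursive_oracle_on_8_tips():
    newick = "(((a:1,b:2):1.5,(c:0.5,d:1):2):1,((e:2,f:1):1,(g:3,h:0.7):0.3):2);"
    rng = np.random.default_rng(50)
    vals = {t: float(v) for t, v in zip("abcdefgh", rng.uniform(1, 100, 8))}
    tree_dict = ((("a", "b"), ("c", "d")), (("e", "f"), ("g", "h")))
    bl = {"a": 1, "b": 2, "c": 0.5, "d": 1, "e": 2, "f": 1, "g": 3, "h": 0.7,
          ("a", "b"): 1.5, ("c", "d"): 2, (("a", "b"), ("c", "d")): 1,
          ("e", "f"): 1, ("g", "h"): 0.3, (("e", "f"), ("g", "h")): 2,
          tree_dict: 0.0}
    assert pic_root_estimate(newick, vals) == pytest.approx(_oracle_pic(tree_dict, bl, vals))


def test_pic_brownian_motion_root_unbiased():
    # simulate Brownian motion down a fixed 16-tip tree; the root estimate
    # must be unbiased for the root state over replicates
    taxa = [f"t{i}" for i in range(16)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=16,
        rng=__import__("random").Random(51),
    )
    for leaf, name in zip(tree.leaf_node_iter(), taxa):
        leaf.taxon.label = name
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(float(edge.length), 0.05)
    newick = tree.as_string(schema="newick")
    rng = np.random.default_rng(52)
    root_true = 5.0
    ests = []
    for _ in range(400):
        vals = {}

        def walk(node, x):
            for ch in node.child_nodes():
                dx = rng.normal(0, math.sqrt(max(ch.edge.length, 1e-9)))
                if ch.is_leaf():
                    vals[ch.taxon.label] = x + dx
                else:
                    walk(ch, x + dx)

        walk(tree.seed_node, root_true)
        ests.append(pic_root_estimate(newick, vals))
    ests = np.array(ests)
    se = ests.std(ddof=1) / math.sqrt(len(ests))
    assert abs(ests.mean() - root_true) < 3 * se + 0.02


def test_pic_polytomy_and_missing_tip_errors():
    with pytest.raises(ValueError, match="polytomy"):
        pic_root_estimate("(a:1,b:1,c:1);", {"a": 1.0, "b": 2.0, "c": 3.0})
    with pytest.raises(ValueError, match="missing"):
        pic_root_estimate("(a:1,b:1);", {"a": 1.0})


def test_pic_dataframe_columns_processed_independently():
    newick = "((a:1,b:1):1,(c:1,d:1):1);"
    df = pd.DataFrame(
        {"mean_len": [100.0, 200.0, 300.0, 400.0], "q1": [10.0, 20.0, 30.0, 40.0]},
        index=["a", "b", "c", "d"],
    )
    res = pic_ancestral(newick, df)
    assert set(res.columns) == {"mean_len", "q1"}
    # Q1 <= mean at every node for these inputs
    assert (res["q1"] <= res["mean_len"]).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_pic_root_matches_ape_ace(tmp_path):
    """Independent oracle: R ape's PIC-based ancestral estimate at the root."""
    newick = "(((a:1,b:2):1.5,(c:0.5,d:1):2):1,(e:2.2,f:0.9):1.1);"
    vals = {"a": 12.0, "b": 7.5, "c": 30.1, "d": 22.0, "e": 5.0, "f": 9.9}
    script = tmp_path / "pic.R"
    script.write_text(
        'library(ape)\n'
        f'tr <- read.tree(text="{newick}")\n'
        f'x <- c(a=12.0, b=7.5, c=30.1, d=22.0, e=5.0, f=9.9)\n'
        'a <- ace(x[tr$tip.label], tr, type="continuous", method="pic")\n'
        'cat(sprintf("%.10f", a$ace[1]))\n'
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    assert pic_root_estimate(newick, vals) == pytest.approx(float(out.stdout), rel=1e-8)


# ---------------------------------------------------------------------------
# unit conversion


@pytest.mark.parametrize(
    "density,expected",
    [(8.8, 12.51), (4.3, 6.11), (0.0, 0.0)],
)
def test_density_unit_conversion_printed_values(density, expected):
    assert round(density_units_convert(density), 2) == pytest.approx(expected)


def test_density_conversion_linear_invertible():
    x = np.array([0.5, 3.3, 7.7, 15.0])
    y = np.array([density_units_convert(v) for v in x])
    assert np.allclose(y / x, 1.422)
    assert np.allclose(y / 1.422, x)
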