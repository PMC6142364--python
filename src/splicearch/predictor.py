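"""ES-incidence prediction from gene architecture.

A binomial logistic regression classifies exons as ES-positive or -negative
from 11 quantitative architecture traits plus the frame-preservation (3n)
boolean. Two-thirds of a balanced event set trains the model; the held-out
third yields the ROC curve, the AUROC with a 95% CI (Hanley–McNeil), and the
optimal probability threshold p* maximizing sensitivity + specificity.

Genome-scale ES incidence (I_ES) is the fraction of internal exons of a
simulated genome whose ES-positive probability exceeds p*. Simulated genomes
draw coherent architectures: introns per gene ~ Poisson(density), log-normal
CDS (natural mean 1422 bp) split into exons, log-normal intron lengths
(natural mean = the input mean), and normal splice-site distances; gene
length is the realized sum of parts. The I_ES landscape is swept over a
40 x 40 grid of intron density (0.5–15, linear) and mean intron length
(10–8000 bp, cubically spaced to densify short introns) — 1600 genomes.

Ancestral intron statistics are estimated by phylogenetically independent
contrasts: Felsenstein's pruning scheme, where each internal node takes the
branch-length-weighted average of its two daughters and passes an extended
branch upward.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

DEFAULT_FEATURES = [
    "gene_length",
    "cds_length",
    "introns_per_gene",
    "event_position",
    "total_intron_exon_ratio",
    "exon_length",
    "upstream_intron_length",
    "downstream_intron_length",
    "local_intron_exon_ratio",
    "ss5_distance",
    "ss3_distance",
]

LOG_FEATURES = [
    "gene_length",
    "cds_length",
    "event_position",
    "exon_length",
    "upstream_intron_length",
    "downstream_intron_length",
]

DENSITY_RANGE = (0.5, 15.0)
LENGTH_RANGE = (10.0, 8000.0)
GRID_SIDE = 40

#: Reference coupling between architecture and ES positivity used by the
#: package's classifier-recovery experiments: short exons, long flanking
#: introns, high intron density/ratios and weak (distant-from-consensus)
#: splice sites all push towards ES — the direction structure seen in real
#: transcriptomes. Coefficients act on the log1p-transformed design.
COUPLED_BETA: dict[str, float] = {
    "const": -1.1,
    "gene_length": 0.0,
    "cds_length": 0.0,
    "introns_per_gene": 0.05,
    "event_position": 0.0,
    "total_intron_exon_ratio": 0.1,
    "exon_length": -0.8,
    "upstream_intron_length": 0.35,
    "downstream_intron_length": 0.35,
    "local_intron_exon_ratio": 0.05,
    "ss5_distance": 0.5,
    "ss3_distance": 0.3,
    "is_3n": 0.3,
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# model


@dataclass
class EsModel:
    """Fitted logistic ES classifier with its held-out performance."""

    feature_names: list[str]
    params: pd.Series  # includes 'const'
    bse: pd.Series
    pvalues: pd.Series
    log_features: list[str]
    threshold: float
    auroc: float
    auroc_ci: tuple[float, float]
    n_train: int
    n_test: int
    deviance_table: pd.DataFrame | None = None

    def design(self, features: pd.DataFrame) -> pd.DataFrame:
        X = features[self.feature_names].astype(float).copy()
        for c in self.log_features:
            X[c] = np.log1p(X[c])
        if "is_3n" in self.feature_names:
            X["is_3n"] = features["is_3n"].astype(float)
        return sm.add_constant(X, has_constant="add")

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = self.design(features)
        return _sigmoid(X.to_numpy() @ self.params.loc[X.columns].to_numpy())

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "log_features": self.log_features,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "threshold": self.threshold,
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EsModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            params=pd.Series(d["params"]),
            bse=pd.Series(d["bse"]),
            pvalues=pd.Series(d["pvalues"]),
            log_features=d["log_features"],
            threshold=d["threshold"],
            auroc=d["auroc"],
            auroc_ci=tuple(d["auroc_ci"]),
            n_train=d["n_train"],
            n_test=d["n_test"],
        )


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float = 0.05) -> tuple[float, float]:
    """Distribution-free AUROC confidence interval."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    threshold: float  # p*
    sensitivity: float
    specificity: float


def roc_and_threshold(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC, AUROC±CI and the threshold maximizing sensitivity + specificity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr + (1 - fpr)
    best = int(np.argmax(youden))
    p_star = float(min(thr[best], scores.max()))  # roc_curve pads thr[0] past max
    ci = hanley_mcneil_ci(auc, int(labels.sum()), int((1 - labels).sum()))
    return RocResult(fpr, tpr, thr, auc, ci, p_star, float(tpr[best]), float(1 - fpr[best]))


def train_es_classifier(
    features: pd.DataFrame,
    labels: Sequence[int],
    feature_names: Sequence[str] | None = None,
    include_3n: bool = True,
    log_length_features: bool = True,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> EsModel:
    """Maximum-likelihood logistic fit on a train split; ROC on the held-out
    test split. Expects a balanced positive/negative event set.

    Length-like predictors are log1p-transformed by default (heavy-tailed).
    Perfect separation falls back to an L2-penalized fit with a warning.
    """
    names = list(feature_names) if feature_names is not None else list(DEFAULT_FEATURES)
    if include_3n and "is_3n" in features.columns and "is_3n" not in names:
        names = names + ["is_3n"]
    logf = [c for c in (LOG_FEATURES if log_length_features else []) if c in names]

    X = features[names].astype(float).copy()
    for c in logf:
        X[c] = np.log1p(X[c])
    X = sm.add_constant(X, has_constant="add")
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_train = int(round(train_fraction * len(X)))
    tr, te = order[:n_train], order[n_train:]

    def _fit(Xd, yd):
        model = sm.Logit(yd, Xd)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=200)
            if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
                raise ValueError("non-finite fit")
            return res, False
        except Exception:
            res = model.fit_regularized(disp=0, alpha=1e-4, maxiter=500)
            return res, True

    res, penalized = _fit(X.iloc[tr], y[tr])
    if penalized:
        warnings.warn("perfect separation detected: penalized logistic fallback used")

    # sequential deviance (type-I) table
    dev_rows = []
    cols = ["const"]
    prev_llf = sm.Logit(y[tr], X.iloc[tr][cols]).fit(disp=0).llf
    for c in [c for c in X.columns if c != "const"]:
        cols.append(c)
        try:
            llf = sm.Logit(y[tr], X.iloc[tr][cols]).fit(disp=0, maxiter=200).llf
        except Exception:
            llf = np.nan
        dev_rows.append((c, 2 * (llf - prev_llf)))
        prev_llf = llf if np.isfinite(llf) else prev_llf
    dev_table = pd.DataFrame(dev_rows, columns=["feature", "deviance_drop"])

    params = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    try:
        bse = pd.Series(np.asarray(res.bse, dtype=float), index=X.columns)
        pvals = pd.Series(np.asarray(res.pvalues, dtype=float), index=X.columns)
    except Exception:
        bse = pd.Series(np.nan, index=X.columns)
        pvals = pd.Series(np.nan, index=X.columns)

    test_scores = _sigmoid(X.iloc[te].to_numpy() @ params.to_numpy())
    roc = roc_and_threshold(test_scores, y[te].astype(int))
    return EsModel(
        feature_names=names,
        params=params,
        bse=bse,
        pvalues=pvals,
        log_features=logf,
        threshold=roc.threshold,
        auroc=roc.auroc,
        auroc_ci=roc.auroc_ci,
        n_train=len(tr),
        n_test=len(te),
        deviance_table=dev_table,
    )


# ---------------------------------------------------------------------------
# simulated genome architectures


@dataclass(frozen=True)
class SimGenomeParams:
    """Architecture-only simulated genome (no sequences)."""

    intron_density: float
    intron_len_mean: float
    n_genes: int = 20_000
    cds_len_mean: float = 1422.0
    cds_log_sd: float = 0.45
    intron_log_sd: float = 0.6
    exon_log_sd: float = 0.6
    ss5_mean: float = 0.6
    ss5_sd: float = 0.3
    ss3_mean: float = 1.2
    ss3_sd: float = 0.5

    def __post_init__(self):
        if self.intron_density < 0:
            raise ValueError("density must be >= 0")
        if self.intron_len_mean <= 0:
            raise ValueError("intron length must be > 0")


def _lognormal(mean: float, log_sd: float, rng: np.random.Generator, size):
    return rng.lognormal(np.log(mean) - log_sd**2 / 2.0, log_sd, size=size)


def simulate_architectures(
    params: SimGenomeParams, n_exons: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Feature table of up to ``n_exons`` random internal exons of one
    simulated genome. Genes with < 2 introns have no internal exons, so fewer
    rows may be returned at low density."""
    rng = np.random.default_rng(seed)
    n_introns = rng.poisson(params.intron_density, size=params.n_genes)
    rows = []
    gene_ids = np.flatnonzero(n_introns >= 2)
    for g in gene_ids:
        N = int(n_introns[g])
        cds = max(150.0, float(_lognormal(params.cds_len_mean, params.cds_log_sd, rng, None)))
        exon_lens = np.maximum(
            3, np.round(_lognormal(cds / (N + 1), params.exon_log_sd, rng, N + 1))
        ).astype(int)
        intron_lens = np.maximum(
            10, np.round(_lognormal(params.intron_len_mean, params.intron_log_sd, rng, N))
        ).astype(int)
        cds_real = int(exon_lens.sum())
        gene_len = cds_real + int(intron_lens.sum())
        total_ratio = intron_lens.sum() / cds_real
        pos = np.concatenate([[0], np.cumsum(exon_lens[:-1] + intron_lens)])
        for e in range(1, N):  # internal exons: flanked by introns e-1 and e
            rows.append((
                g, e, gene_len, cds_real, N, int(pos[e]), total_ratio,
                int(exon_lens[e]), int(intron_lens[e - 1]), int(intron_lens[e]),
                (intron_lens[e - 1] + intron_lens[e]) / (2.0 * exon_lens[e]),
                exon_lens[e] % 3 == 0,
            ))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "exon_index", "gene_length", "cds_length", "introns_per_gene",
            "event_position", "total_intron_exon_ratio", "exon_length",
            "upstream_intron_length", "downstream_intron_length",
            "local_intron_exon_ratio", "is_3n",
        ],
    )
    df["ss5_distance"] = np.clip(rng.normal(params.ss5_mean, params.ss5_sd, len(df)), 0, None)
    df["ss3_distance"] = np.clip(rng.normal(params.ss3_mean, params.ss3_sd, len(df)), 0, None)
    if len(df) > n_exons:
        keep = np.sort(rng.choice(len(df), size=n_exons, replace=False))
        df = df.iloc[keep].reset_index(drop=True)
    return df


def plant_es_labels(
    features: pd.DataFrame,
    beta: Mapping[str, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli labels from a known logistic model over the (log1p) design —
    the ground truth for classifier-recovery experiments."""
    b = dict(COUPLED_BETA if beta is None else beta)
    rng = np.random.default_rng(seed)
    lin = np.full(len(features), b.get("const", 0.0))
    for name, coef in b.items():
        if name == "const" or coef == 0.0:
            continue
        col = features[name].astype(float).to_numpy()
        if name in LOG_FEATURES:
            col = np.log1p(col)
        lin = lin + coef * col
    return (rng.random(len(features)) < _sigmoid(lin)).astype(int)


def true_model_scores(features: pd.DataFrame, beta: Mapping[str, float] | None = None) -> np.ndarray:
    """Oracle p_ES from the planted coefficients (no fitting)."""
    b = dict(COUPLED_BETA if beta is None else beta)
    lin = np.full(len(features), b.get("const", 0.0))
    for name, coef in b.items():
        if name == "const" or coef == 0.0:
            continue
        col = features[name].astype(float).to_numpy()
        if name in LOG_FEATURES:
            col = np.log1p(col)
        lin = lin + coef * col
    return _sigmoid(lin)


def balance_classes(
    features: pd.DataFrame, labels: np.ndarray, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Equal-size positive/negative subsample (the balanced training design)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n = min(len(pos), len(neg))
    if n == 0:
        raise ValueError("need both classes present")
    keep = np.sort(np.concatenate([
        rng.choice(pos, n, replace=False), rng.choice(neg, n, replace=False)
    ]))
    return features.iloc[keep].reset_index(drop=True), labels[keep]


def compute_ies(features: pd.DataFrame, model: EsModel, threshold: float | None = None) -> float:
    """Fraction of exons with p_ES above the optimal threshold."""
    if len(features) == 0:
        return math.nan
    thr = model.threshold if threshold is None else threshold
    return float(np.mean(model.predict_proba(features) > thr))


def grid_axes(
    n_density: int = GRID_SIDE,
    n_length: int = GRID_SIDE,
    density_range: tuple[float, float] = DENSITY_RANGE,
    length_range: tuple[float, float] = LENGTH_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Density axis at regular intervals; length axis at cubic distances
    (denser at short intron lengths)."""
    d = np.linspace(density_range[0], density_range[1], n_density)
    i = np.arange(n_length) / (n_length - 1)
    l = length_range[0] + (length_range[1] - length_range[0]) * i**3
    return d, l


def ies_grid_sweep(
    model: EsModel,
    n_density: int = GRID_SIDE,
    n_length: int = GRID_SIDE,
    density_range: tuple[float, float] = DENSITY_RANGE,
    length_range: tuple[float, float] = LENGTH_RANGE,
    n_genes: int = 20_000,
    n_exons: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """I_ES over the density x length grid (default 40 x 40 = 1600 genomes)."""
    dens, lens = grid_axes(n_density, n_length, density_range, length_range)
    ss = np.random.SeedSequence(seed)
    cell_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(dens) * len(lens))]
    rows = []
    k = 0
    for d in dens:
        for L in lens:
            feats = simulate_architectures(
                SimGenomeParams(intron_density=float(d), intron_len_mean=float(L), n_genes=n_genes),
                n_exons=n_exons,
                seed=cell_seeds[k],
            )
            rows.append((float(d), float(L), len(feats), compute_ies(feats, model)))
            k += 1
    return pd.DataFrame(rows, columns=["intron_density", "intron_len_mean", "n_exons", "ies"])


def real_vs_simulated_ies(
    real_genomes: pd.DataFrame,
    grid: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Pair each real genome's I_ES with the nearest simulated-grid cell.

    ``real_genomes`` needs columns intron_density, intron_len_mean, ies.
    Nearest cell is chosen in (density, cube-root length) space, matching the
    grid's spacing; out-of-range genomes are clamped with a warning.
    Returns the paired table and the linear-fit summary (R², slope, p).
    """
    d_axis = np.sort(grid["intron_density"].unique())
    l_axis = np.sort(grid["intron_len_mean"].unique())
    rows = []
    for _, g in real_genomes.iterrows():
        d, L = float(g["intron_density"]), float(g["intron_len_mean"])
        if not (d_axis[0] <= d <= d_axis[-1]) or not (l_axis[0] <= L <= l_axis[-1]):
            warnings.warn(f"genome outside grid range (density={d}, length={L}): clamped")
            d = float(np.clip(d, d_axis[0], d_axis[-1]))
            L = float(np.clip(L, l_axis[0], l_axis[-1]))
        dn = d_axis[np.argmin(np.abs(d_axis - d))]
        ln = l_axis[np.argmin(np.abs(np.cbrt(l_axis) - np.cbrt(L)))]
        cell = grid[(grid["intron_density"] == dn) & (grid["intron_len_mean"] == ln)].iloc[0]
        rows.append((g.get("genome_id", len(rows)), float(g["ies"]), float(cell["ies"]), dn, ln))
    paired = pd.DataFrame(rows, columns=["genome_id", "ies_real", "ies_simulated", "cell_density", "cell_length"])
    if len(paired) >= 3:
        fit = stats.linregress(paired["ies_real"], paired["ies_simulated"])
        summary = {"r_squared": fit.rvalue**2, "slope": fit.slope, "slope_p": fit.pvalue, "intercept": fit.intercept}
    else:
        summary = {"r_squared": math.nan, "slope": math.nan, "slope_p": math.nan, "intercept": math.nan}
    return paired, summary


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    s = str(tree)
    if Path(s).exists() if len(s) < 260 and "\n" not in s and "(" not in s else False:
        return dendropy.Tree.get(path=s, schema="newick")
    return dendropy.Tree.get(data=s, schema="newick")


def pic_ancestral(tree, tip_values: Mapping[str, float] | pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Ancestral values at every internal node via Felsenstein pruning.

    Each internal node's estimate is the branch-length-weighted average of
    its two daughters' estimates; the node's branch to its parent is extended
    by l1*l2/(l1+l2). The tree must be fully resolved with positive branch
    lengths; every tip must have a value. With a DataFrame, each column is
    estimated independently (mean/median/Q1/Q3 intron lengths, say).
    """
    t = _as_tree(tree)
    if isinstance(tip_values, pd.DataFrame):
        cols = {c: pic_ancestral(t, tip_values[c])["estimate"] for c in tip_values.columns}
        return pd.DataFrame(cols)
    if isinstance(tip_values, pd.Series):
        tip_values = tip_values.to_dict()

    tips = [lf.taxon.label for lf in t.leaf_node_iter()]
    missing = [x for x in tips if x not in tip_values]
    if missing:
        raise ValueError(f"missing tip values: {missing}")

    estimates: dict[str, float] = {}
    counter = [0]

    def label(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        node.label = f"node{counter[0]}"
        return node.label

    def prune(node) -> tuple[float, float]:
        if node.is_leaf():
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise ValueError(f"tip {node.taxon.label} needs a positive branch length")
            return float(tip_values[node.taxon.label]), float(bl)
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                "tree has a polytomy (or unifurcation); resolve it before PIC analysis"
            )
        x1, l1 = prune(children[0])
        x2, l2 = prune(children[1])
        v = (x1 / l1 + x2 / l2) / (1 / l1 + 1 / l2)
        estimates[label(node)] = v
        bl = node.edge.length if node.edge.length else 0.0
        return v, float(bl) + l1 * l2 / (l1 + l2)

    root = t.seed_node
    prune(root)
    out = pd.DataFrame({"estimate": pd.Series(estimates)})
    out.attrs["root"] = label(root)
    return out


def pic_root_estimate(tree, tip_values) -> float:
    res = pic_ancestral(tree, tip_values)
    return float(res.loc[res.attrs["root"], "estimate"])


def density_units_convert(introns_per_cds_kbp: float, mean_cds_kbp: float = 1.422) -> float:
    """introns/CDS kbp -> introns/gene, via the cross-species mean CDS length
    (1.422 kbp). Linear and invertible."""
    return introns_per_cds_kbp * mean_cds_kbp
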