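"""Gene-architecture features and association statistics for AS events.

Features recorded per event (exon for ES, intron for IR): gene and CDS
lengths, introns per gene, event position from the start codon (pre-mRNA
coordinates), total and local intron/exon length ratios, event length and
flanking-element lengths, GC contents and their differential
(dGC = GC_intron - GC_exon), splice-site PWM distances, frame preservation
(3n), and optionally expression (cRPKM).

Splice-site scoring uses position-weight matrices built from all annotated
sites of the genome: the 5' window is 9 bp (3 exonic + 6 intronic), the 3'
window 23 bp (20 intronic + 3 exonic). The distance of a site from the
consensus is the per-position consensus-frequency deficit summed over
positions — zero only for the per-position consensus sequence, and weighting
mismatches by how conserved each position is.

Association statistics: two complementary one-sided two-sample KS tests give
a signed D (positive when the positive-class distribution is stochastically
greater, at p < 0.01 in exactly one direction, else NA); Fisher's exact test
for 3n enrichment; Spearman rank correlation for monotone trends; and a
rank-based relative-expression score for the core spliceosome gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genemodel import GeneModel

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

FIVE_PRIME_WINDOW = (3, 6)  # exonic, intronic bp
THREE_PRIME_WINDOW = (20, 3)  # intronic, exonic bp

ES_FEATURES = [
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


def gc_content(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class SpliceSiteModel:
    """PWMs over the 5' (9-bp) and 3' (23-bp) splice-site windows."""

    pwm5: np.ndarray  # 4 x 9, columns sum to 1
    pwm3: np.ndarray  # 4 x 23
    pseudo: float = 1e-4

    def __post_init__(self):
        if self.pwm5.shape != (4, 9) or self.pwm3.shape != (4, 23):
            raise ValueError("5' window is 9 bp, 3' window is 23 bp")


def build_pwm(sites: Sequence[str], pseudo: float = 1e-4) -> np.ndarray:
    """Column-stochastic base-frequency matrix (rows A,C,G,T) from aligned sites."""
    if not sites:
        raise ValueError("no sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("all sites must share the model window length")
    m = np.full((4, L), pseudo)
    for s in sites:
        for i, b in enumerate(s):
            k = _BASE_INDEX.get(b)
            if k is not None:
                m[k, i] += 1.0
    return m / m.sum(axis=0, keepdims=True)


def score_site(seq: str, pwm: np.ndarray) -> float:
    """Distance from consensus: sum over positions of f_max - f_observed.

    Positions carrying a non-ACGT base (N) are skipped.
    """
    if len(seq) != pwm.shape[1]:
        raise ValueError(f"site length {len(seq)} != model window {pwm.shape[1]}")
    fmax = pwm.max(axis=0)
    d = 0.0
    for i, b in enumerate(seq):
        k = _BASE_INDEX.get(b)
        if k is None:
            continue
        d += fmax[i] - pwm[k, i]
    return d


def splice_site_windows(
    model: GeneModel, genome: Mapping[str, str]
) -> list[tuple[int, str, str]]:
    """(intron_index, 5' 9-mer, 3' 23-mer) for each intron with long-enough
    flanks; windows are transcript-oriented."""
    ex = model.exon_seqs(genome)
    intr = model.intron_seqs(genome)
    e5, i5 = FIVE_PRIME_WINDOW
    i3, e3 = THREE_PRIME_WINDOW
    out = []
    for i, iseq in enumerate(intr):
        if len(ex[i]) < e5 or len(ex[i + 1]) < e3 or len(iseq) < i5 + i3:
            continue
        w5 = ex[i][-e5:] + iseq[:i5]
        w3 = iseq[-i3:] + ex[i + 1][:e3]
        out.append((i, w5, w3))
    return out


def build_splice_site_model(
    models: Mapping[str, GeneModel], genome: Mapping[str, str], pseudo: float = 1e-4
) -> SpliceSiteModel:
    s5, s3 = [], []
    for gid in sorted(models):
        for _, w5, w3 in splice_site_windows(models[gid], genome):
            s5.append(w5)
            s3.append(w3)
    if not s5:
        raise ValueError("no splice sites in annotation")
    return SpliceSiteModel(build_pwm(s5, pseudo), build_pwm(s3, pseudo), pseudo)


def _gene_level(model: GeneModel) -> dict:
    ex = model.exon_lengths()
    intr = model.intron_lengths()
    return {
        "gene_length": sum(ex) + sum(intr),
        "cds_length": sum(ex),
        "introns_per_gene": len(intr),
        "total_intron_exon_ratio": (sum(intr) / sum(ex)) if sum(ex) else math.nan,
    }


def extract_features_es(
    models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    ss_model: SpliceSiteModel,
    expression: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Architecture vector for every internal exon of every gene.

    Intron GC is the mean over the two flanking introns; the exon's splice
    sites are the 3' site of its upstream intron and the 5' site of its
    downstream intron.
    """
    rows = []
    for gid in sorted(models):
        m = models[gid]
        if m.n_exons < 3:
            continue
        gene = _gene_level(m)
        ex_seqs = m.exon_seqs(genome)
        in_seqs = m.intron_seqs(genome)
        windows = {i: (w5, w3) for i, w5, w3 in splice_site_windows(m, genome)}
        ex_lens = m.exon_lengths()
        in_lens = m.intron_lengths()
        for e in range(1, m.n_exons - 1):
            up_i, down_i = e - 1, e
            gc_ex = gc_content(ex_seqs[e])
            gc_in = float(np.mean([gc_content(in_seqs[up_i]), gc_content(in_seqs[down_i])]))
            ss3 = score_site(windows[up_i][1], ss_model.pwm3) if up_i in windows else math.nan
            ss5 = score_site(windows[down_i][0], ss_model.pwm5) if down_i in windows else math.nan
            rows.append({
                "gene_id": gid,
                "exon_index": e,
                **gene,
                "event_position": m.event_position(e, "exon"),
                "exon_length": ex_lens[e],
                "upstream_intron_length": in_lens[up_i],
                "downstream_intron_length": in_lens[down_i],
                "local_intron_exon_ratio": (in_lens[up_i] + in_lens[down_i]) / (2.0 * ex_lens[e]),
                "gc_ex": gc_ex,
                "gc_in": gc_in,
                "dgc_in_ex": gc_in - gc_ex,
                "ss5_distance": ss5,
                "ss3_distance": ss3,
                "is_3n": ex_lens[e] % 3 == 0,
                "crpkm": expression.get(gid, math.nan) if expression else math.nan,
            })
    return pd.DataFrame(rows)


def extract_features_ir(
    models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    ss_model: SpliceSiteModel,
    expression: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Architecture vector for every intron (exon GC is the flanking-exon mean)."""
    rows = []
    for gid in sorted(models):
        m = models[gid]
        if m.n_introns == 0:
            continue
        gene = _gene_level(m)
        ex_seqs = m.exon_seqs(genome)
        in_seqs = m.intron_seqs(genome)
        windows = {i: (w5, w3) for i, w5, w3 in splice_site_windows(m, genome)}
        ex_lens = m.exon_lengths()
        in_lens = m.intron_lengths()
        for i in range(m.n_introns):
            gc_in = gc_content(in_seqs[i])
            gc_ex = float(np.mean([gc_content(ex_seqs[i]), gc_content(ex_seqs[i + 1])]))
            ss5 = score_site(windows[i][0], ss_model.pwm5) if i in windows else math.nan
            ss3 = score_site(windows[i][1], ss_model.pwm3) if i in windows else math.nan
            rows.append({
                "gene_id": gid,
                "intron_index": i,
                **gene,
                "event_position": m.event_position(i, "intron"),
                "intron_length": in_lens[i],
                "upstream_exon_length": ex_lens[i],
                "downstream_exon_length": ex_lens[i + 1],
                "local_intron_exon_ratio": 2.0 * in_lens[i] / (ex_lens[i] + ex_lens[i + 1]),
                "gc_ex": gc_ex,
                "gc_in": gc_in,
                "dgc_in_ex": gc_in - gc_ex,
                "ss5_distance": ss5,
                "ss3_distance": ss3,
                "is_3n": in_lens[i] % 3 == 0,
                "crpkm": expression.get(gid, math.nan) if expression else math.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    feature: str
    d_signed: float  # NaN when not significant in exactly one direction
    p_greater: float  # H1: positive-class values stochastically greater
    p_less: float
    sign: int  # +1, -1, or 0 (NA)


def signed_ks(
    values_positive: Sequence[float],
    values_negative: Sequence[float],
    alpha: float = 0.01,
    feature: str = "",
) -> AssociationResult:
    """Two complementary one-sided two-sample KS tests with a signed D.

    D takes the positive sign when the positive-class distribution is
    stochastically greater at p < alpha, the negative sign in the opposite
    case, and NA when neither or both tests are significant.
    """
    pos = np.asarray(values_positive, dtype=float)
    neg = np.asarray(values_negative, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both samples must be non-empty")
    # scipy alternative='less': H1 is F_pos < F_neg, i.e. positives greater
    ks_greater = stats.ks_2samp(pos, neg, alternative="less")
    ks_less = stats.ks_2samp(pos, neg, alternative="greater")
    sig_g = ks_greater.pvalue < alpha
    sig_l = ks_less.pvalue < alpha
    if sig_g and not sig_l:
        return AssociationResult(feature, float(ks_greater.statistic), ks_greater.pvalue, ks_less.pvalue, 1)
    if sig_l and not sig_g:
        return AssociationResult(feature, -float(ks_less.statistic), ks_greater.pvalue, ks_less.pvalue, -1)
    return AssociationResult(feature, math.nan, ks_greater.pvalue, ks_less.pvalue, 0)


def fisher_3n(
    pos_3n: int, pos_non3n: int, neg_3n: int, neg_non3n: int, alpha: float = 0.01
) -> dict:
    """Fisher's exact test for frame-preservation (3n) enrichment in
    positive vs negative events."""
    table = [[pos_3n, pos_non3n], [neg_3n, neg_non3n]]
    if min(min(r) for r in table) < 0:
        raise ValueError("counts must be non-negative")
    oddsratio, p = stats.fisher_exact(table, alternative="two-sided")
    sign = 0
    if p < alpha:
        sign = 1 if oddsratio > 1 else -1
    return {"odds_ratio": oddsratio, "p": p, "sign": sign, "alpha": alpha}


def spearman_assoc(x: Sequence[float], y: Sequence[float], alpha: float = 0.01) -> dict:
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "significant": bool(p < alpha)}


def association_matrix(
    features_positive: pd.DataFrame,
    features_negative: pd.DataFrame,
    feature_cols: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Signed-KS association of each feature with event positivity (the
    heatmap row for one species)."""
    rows = []
    for col in feature_cols:
        res = signed_ks(
            features_positive[col].to_numpy(),
            features_negative[col].to_numpy(),
            alpha=alpha,
            feature=col,
        )
        rows.append((col, res.d_signed, res.sign, res.p_greater, res.p_less))
    return pd.DataFrame(rows, columns=["feature", "d_signed", "sign", "p_greater", "p_less"])


def spliceosome_rank_score(
    expression: pd.Series,
    spliceosome_genes: Sequence[str],
    n_subsets: int = 500,
    subset_size: int = 199,
    seed: int = 0,
) -> float:
    """Relative-expression rank of the core spliceosome gene set.

    For each of ``n_subsets`` random gene subsets (size ``subset_size``,
    sampled with replacement), each spliceosomal gene is inserted and ranked
    1..subset_size+1 (1 = lowest expression; ties take mid-ranks). The score
    is the grand mean rank over genes and subsets — near
    (subset_size + 2) / 2 when spliceosome expression is exchangeable with
    the genome background, and near subset_size + 1 when it dominates.
    """
    splice = [g for g in spliceosome_genes if g in expression.index]
    if not splice:
        raise ValueError("no spliceosomal gene has expression data")
    rng = np.random.default_rng(seed)
    values = expression.to_numpy(dtype=float)
    svals = expression.loc[splice].to_numpy(dtype=float)
    total = 0.0
    for _ in range(n_subsets):
        subset = np.sort(rng.choice(values, size=subset_size, replace=True))
        less = np.searchsorted(subset, svals, side="left")
        upto = np.searchsorted(subset, svals, side="right")
        ranks = less + 1 + (upto - less) / 2.0  # mid-rank among subset + itself
        total += ranks.sum()
    return total / (n_subsets * len(splice))
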