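"""From corrected junction counts to event rates, classes, and species profiles.

Rates
-----
Exon skipping, per middle exon::

    r_ES = m_E1E3 / ((m_E1E2 + m_E2E3)/2 + m_E1E3)

Intron retention, per intron::

    r_IR = (m_IE + m_EI)/2 / (m_EE + (m_IE + m_EI)/2)

where m are mappability-corrected read counts (raw / (n_effective/35)).

Classification (corrected counts):

* ES-positive: sum > 10, m_E1E2 > 2, m_E2E3 > 2, m_E1E3 > 1, 0.10 <= r < 0.90
* ES-negative: sum > 10, m_E1E2 > 2, m_E2E3 > 2, r < 0.10
* IR-positive: sum > 10, m_IE > 1, m_EI > 1, m_EE > 2, 0.10 <= r < 0.90
* IR-negative: sum > 10, m_EE > 2, r < 0.10
* otherwise undetermined. The three statuses partition all events.

Species-level frequency (F_ES,sp / F_IR,sp): classifiable events are split
into random disjoint bins of 100 events; per bin, the reads assigned to the
bin's junctions are subsampled without replacement to 10,000 (multivariate
hypergeometric over per-junction counts), rates are recomputed from the
subsample, and the bin value is the unweighted mean rate (percent) over
events with a defined rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import EsTriplet, IrTriad

MAX_THEORETICAL_MAPPABILITY = 35

POSITIVE = "positive"
NEGATIVE = "negative"
UNDETERMINED = "undetermined"


def correct_counts(
    raw: float, n_effective: int, max_theoretical: int = MAX_THEORETICAL_MAPPABILITY
) -> float:
    """Mappability correction: raw / (n_effective / max_theoretical)."""
    if n_effective <= 0:
        raise ValueError("junction with non-positive effective mappability should have been filtered")
    return raw / (n_effective / max_theoretical)


def compute_r_es(m_e1e2: float, m_e2e3: float, m_e1e3: float) -> float:
    """ES rate of the middle exon; NaN when the denominator is zero."""
    denom = (m_e1e2 + m_e2e3) / 2.0 + m_e1e3
    if denom == 0:
        return math.nan
    return m_e1e3 / denom


def compute_r_ir(m_ie: float, m_ei: float, m_ee: float) -> float:
    """IR rate of the intron; NaN when the denominator is zero."""
    ret = (m_ie + m_ei) / 2.0
    denom = m_ee + ret
    if denom == 0:
        return math.nan
    return ret / denom


def classify_es(m_e1e2: float, m_e2e3: float, m_e1e3: float, r_es: float) -> str:
    cov = (m_e1e2 + m_e2e3 + m_e1e3) > 10 and m_e1e2 > 2 and m_e2e3 > 2
    if cov and not math.isnan(r_es):
        if m_e1e3 > 1 and 0.10 <= r_es < 0.90:
            return POSITIVE
        if r_es < 0.10:
            return NEGATIVE
    return UNDETERMINED


def classify_ir(m_ie: float, m_ei: float, m_ee: float, r_ir: float) -> str:
    cov = (m_ie + m_ei + m_ee) > 10 and m_ee > 2
    if cov and not math.isnan(r_ir):
        if m_ie > 1 and m_ei > 1 and 0.10 <= r_ir < 0.90:
            return POSITIVE
        if r_ir < 0.10:
            return NEGATIVE
    return UNDETERMINED


def _corrected(counts: Mapping[str, float], eff: Mapping[str, int], jid: str) -> float:
    return correct_counts(counts.get(jid, 0), eff[jid])


def quantify_es(
    triplets: Sequence[EsTriplet],
    counts: Mapping[str, float],
    mappability: pd.DataFrame,
) -> pd.DataFrame:
    """Per-triplet corrected counts, r_ES and status.

    Triplets with any junction failing the mappability filter get
    ``passed=False`` and no rate (they were never mapping targets).
    """
    eff = mappability["n_effective"].to_dict()
    passed = mappability["passed"].to_dict()
    rows = []
    for t in triplets:
        ok = all(passed.get(j, False) for j in t.junction_ids)
        if ok:
            m12 = _corrected(counts, eff, t.j_incl1)
            m23 = _corrected(counts, eff, t.j_incl2)
            m13 = _corrected(counts, eff, t.j_skip)
            r = compute_r_es(m12, m23, m13)
            status = classify_es(m12, m23, m13, r)
        else:
            m12 = m23 = m13 = math.nan
            r, status = math.nan, UNDETERMINED
        rows.append(
            (t.gene_id, t.e2, t.middle_len, t.is_3n, t.j_incl1, t.j_incl2, t.j_skip,
             ok, m12, m23, m13, r, status)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "exon_index", "exon_length", "is_3n",
            "j_incl1", "j_incl2", "j_skip", "passed",
            "m_e1e2", "m_e2e3", "m_e1e3", "r_es", "status",
        ],
    )


def quantify_ir(
    triads: Sequence[IrTriad],
    counts: Mapping[str, float],
    mappability: pd.DataFrame,
) -> pd.DataFrame:
    eff = mappability["n_effective"].to_dict()
    passed = mappability["passed"].to_dict()
    rows = []
    for t in triads:
        ok = all(passed.get(j, False) for j in t.junction_ids)
        if ok:
            mei = _corrected(counts, eff, t.j_ei)
            mie = _corrected(counts, eff, t.j_ie)
            mee = _corrected(counts, eff, t.j_ee)
            r = compute_r_ir(mie, mei, mee)
            status = classify_ir(mie, mei, mee, r)
        else:
            mei = mie = mee = math.nan
            r, status = math.nan, UNDETERMINED
        rows.append(
            (t.gene_id, t.intron_index, t.intron_len, t.is_3n,
             t.j_ei, t.j_ie, t.j_ee, ok, mei, mie, mee, r, status)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "intron_index", "intron_length", "is_3n",
            "j_ei", "j_ie", "j_ee", "passed",
            "m_ei", "m_ie", "m_ee", "r_ir", "status",
        ],
    )


@dataclass
class SpeciesProfile:
    """Binned species-level AS frequency distribution (percent scale)."""

    bin_values: np.ndarray  # mean rate per bin, 0–100
    bin_events: list[list[int]]  # row indices of the event table per bin
    reads_subsampled: list[int]
    reads_requested: int
    seed: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)


def species_frequency(
    events: pd.DataFrame,
    counts: Mapping[str, float],
    mappability: pd.DataFrame,
    kind: str,
    n_bins: int = 100,
    bin_size: int = 100,
    reads_per_bin: int = 10_000,
    seed: int = 0,
) -> SpeciesProfile:
    """Binned per-species AS frequency distribution.

    ``events`` is the output of :func:`quantify_es` / :func:`quantify_ir`;
    only classifiable (positive/negative) events enter bins. Species with
    fewer classifiable events than ``n_bins * bin_size`` yield as many full
    bins as possible, with a warning.
    """
    if kind not in ("es", "ir"):
        raise ValueError(kind)
    jcols = ("j_incl1", "j_incl2", "j_skip") if kind == "es" else ("j_ei", "j_ie", "j_ee")
    rng = np.random.default_rng(seed)
    eff = mappability["n_effective"].to_dict()
    classifiable = events.index[events["status"].isin([POSITIVE, NEGATIVE])].to_numpy()
    n_full = min(n_bins, len(classifiable) // bin_size)
    if n_full < n_bins:
        warnings.warn(
            f"only {len(classifiable)} classifiable events: emitting {n_full} bins of {bin_size}"
        )
    if n_full == 0:
        return SpeciesProfile(np.array([]), [], [], reads_per_bin, seed)
    order = rng.permutation(classifiable)
    bins = [order[i * bin_size : (i + 1) * bin_size] for i in range(n_full)]

    values, subsampled = [], []
    for bin_idx in bins:
        sub = events.loc[bin_idx]
        jids = sorted({j for _, row in sub.iterrows() for j in (row[jcols[0]], row[jcols[1]], row[jcols[2]])})
        raw = np.array([int(counts.get(j, 0)) for j in jids])
        total = int(raw.sum())
        take = min(reads_per_bin, total)
        if take < total:
            drawn = rng.multivariate_hypergeometric(raw, take)
        else:
            drawn = raw
        dmap = dict(zip(jids, drawn))
        rates = []
        for _, row in sub.iterrows():
            a = correct_counts(dmap[row[jcols[0]]], eff[row[jcols[0]]])
            b = correct_counts(dmap[row[jcols[1]]], eff[row[jcols[1]]])
            c = correct_counts(dmap[row[jcols[2]]], eff[row[jcols[2]]])
            r = compute_r_es(a, b, c) if kind == "es" else compute_r_ir(b, a, c)
            if not math.isnan(r):
                rates.append(r)
        values.append(100.0 * float(np.mean(rates)) if rates else math.nan)
        subsampled.append(take)
    return SpeciesProfile(np.array(values), [list(b) for b in bins], subsampled, reads_per_bin, seed)


def downsample_reads(reads: Sequence, fraction: float | None = None, n: int | None = None, seed: int = 0):
    """Uniform subsample without replacement, exact size, order-preserving."""
    if (fraction is None) == (n is None):
        raise ValueError("give exactly one of fraction or n")
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        n = int(round(fraction * len(reads)))
    if n > len(reads):
        raise ValueError("cannot subsample more reads than available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in keep]


def compute_crpkm(
    gene_counts: Mapping[str, float],
    effective_positions: Mapping[str, int],
    total_assigned: float,
) -> pd.DataFrame:
    """Mappability-corrected RPKM: count / (effective kbp x million reads).

    The denominator length is the count of effectively mappable read start
    positions of the transcript (in kbp-equivalents), not its raw length.
    """
    rows = []
    for gid in sorted(effective_positions):
        cnt = float(gene_counts.get(gid, 0))
        eff = effective_positions[gid]
        if eff <= 0 or total_assigned <= 0:
            val = math.nan if cnt > 0 else 0.0
        else:
            val = cnt / ((eff / 1000.0) * (total_assigned / 1e6))
        rows.append((gid, cnt, eff, val))
    return pd.DataFrame(rows, columns=["gene_id", "count", "effective_positions", "crpkm"])
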