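"""Synthetic genomes, planted alternative-splicing truth, and 50-bp reads.

The generator emulates the statistical structure the downstream analysis
assumes: multi-exonic genes with Poisson intron counts, log-normal CDS and
intron lengths (natural-scale means are the stated parameters), GT..AG introns
carrying a consensus-with-noise splice-site signal, log-normal per-gene
expression, and uniform single-end read sampling from the per-read realized
isoform mixture.

Truth models
------------
``isolated`` (default)
    at most one alternative event per gene — one skipped internal exon *or*
    one retained intron, with its rate drawn from a small set of planted
    values. Sparse events keep the junction-ratio estimators unconfounded by
    neighbouring events, mirroring the low per-exon AS incidence of real
    transcriptomes.
``independent``
    every internal exon / intron draws its own rate independently.
``coupled``
    skip rates are logistic in local architecture (log exon length, log
    flanking intron lengths), for end-to-end classifier-recovery experiments.

Read sampling: each read realizes its own isoform (Bernoulli skip/retention
draws), then a start position is drawn uniformly over the *pre-mRNA* length
and rejected if it falls past the realized isoform's last valid start. This
equalizes read intensity per isoform position across isoforms, so junction
read ratios converge to the planted rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genemodel import GeneModel
from .io import revcomp, write_fasta, write_fastq

BASES = np.frombuffer(b"ACGT", dtype="S1")

# splice-site consensus, transcript orientation
FIVE_PRIME_EXON = "CAG"  # last 3 nt of upstream exon
FIVE_PRIME_INTRON = "GTAAGT"  # first 6 nt of intron
THREE_PRIME_INTRON = "CTCTCTTTTTTTTTTTGCAG"  # last 20 nt of intron
THREE_PRIME_EXON = "GCT"  # first 3 nt of downstream exon

MIN_INTRON = len(FIVE_PRIME_INTRON) + len(THREE_PRIME_INTRON)  # 26 bp
MIN_EXON = 3


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    Length means are natural-scale (the log-normal mu is derived from them),
    matching how mean lengths are quoted for real genomes.
    """

    n_genes: int = 1000
    intron_density: float = 4.0  # mean introns per gene (Poisson)
    intron_len_mean: float = 300.0
    intron_len_log_sd: float = 0.6
    cds_len_mean: float = 1422.0
    cds_len_log_sd: float = 0.45
    gc_exon: float = 0.52
    gc_intron: float = 0.42
    ss_noise: float = 0.05  # per-position substitution rate at splice sites
    expression_log_sd: float = 1.0
    flank: int = 100  # intergenic padding on each side of the gene
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.intron_density < 0:
            raise ValueError("intron_density must be >= 0")
        for name in ("intron_len_mean", "cds_len_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gc_exon", "gc_intron", "ss_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TruthConfig:
    mode: str = "isolated"  # isolated | independent | coupled
    skip_choices: tuple[float, ...] = (0.0, 0.3, 0.5)
    retention_choices: tuple[float, ...] = (0.0, 0.3, 0.5)
    # coupled mode: psi = sigmoid(b0 + b1*log(exon_len) + b2*log(up_intron) + b3*log(down_intron))
    coupling_beta: tuple[float, float, float, float] = (0.0, -1.0, 0.5, 0.5)

    def __post_init__(self):
        if self.mode not in ("isolated", "independent", "coupled"):
            raise ValueError(f"unknown truth mode {self.mode!r}")
        for v in self.skip_choices + self.retention_choices:
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class AsTruth:
    """Planted per-event truth: skip rate per internal exon, retention rate
    per intron, expression weight per gene."""

    exons: pd.DataFrame  # gene_id, exon_index, psi
    introns: pd.DataFrame  # gene_id, intron_index, retention
    genes: pd.DataFrame  # gene_id, expression

    def psi(self, gene_id: str, exon_index: int) -> float:
        return self._psi_map[(gene_id, exon_index)]

    def retention(self, gene_id: str, intron_index: int) -> float:
        return self._ret_map[(gene_id, intron_index)]

    def expression(self, gene_id: str) -> float:
        return self._expr_map[gene_id]

    def __post_init__(self):
        self._psi_map = {
            (g, i): p for g, i, p in self.exons[["gene_id", "exon_index", "psi"]].itertuples(index=False)
        }
        self._ret_map = {
            (g, i): r
            for g, i, r in self.introns[["gene_id", "intron_index", "retention"]].itertuples(index=False)
        }
        self._expr_map = dict(zip(self.genes["gene_id"], self.genes["expression"]))


@dataclass
class SyntheticGenome:
    spec: GenomeSpec
    genome: dict[str, str]
    models: dict[str, GeneModel]
    truth: AsTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        (outdir / "annotation.gff3").write_text(self.gff3())
        self.truth.exons.to_csv(outdir / "truth_exons.tsv", sep="\t", index=False)
        self.truth.introns.to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        (outdir / "spec.json").write_text(json.dumps(dataclasses.asdict(self.spec), indent=1))

    def gff3(self) -> str:
        lines = ["##gff-version 3"]
        for contig in self.genome:
            lines.append(f"##sequence-region {contig} 1 {len(self.genome[contig])}")
        for gid in self.models:
            m = self.models[gid]
            gs, ge = m.span
            tid = m.transcript_id
            lines.append(
                f"{m.contig}\tsplicearch\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\tID={gid}"
            )
            lines.append(
                f"{m.contig}\tsplicearch\tmRNA\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\tID={tid};Parent={gid}"
            )
            # phases in transcript order
            phases: dict[tuple[int, int], int] = {}
            cum = 0
            for iv in m.exons_tx:
                phases[iv] = (3 - cum % 3) % 3
                cum += iv[1] - iv[0]
            for k, (s, e) in enumerate(m.exons):
                lines.append(
                    f"{m.contig}\tsplicearch\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{k};Parent={tid}"
                )
                lines.append(
                    f"{m.contig}\tsplicearch\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                    f"ID={tid}.cds{k};Parent={tid}"
                )
        return "\n".join(lines) + "\n"


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _noisy(consensus: str, noise: float, rng: np.random.Generator) -> np.ndarray:
    arr = np.frombuffer(consensus.encode(), dtype="S1").copy()
    hits = rng.random(len(arr)) < noise
    for i in np.flatnonzero(hits):
        others = BASES[BASES != arr[i]]
        arr[i] = rng.choice(others)
    return arr


def _draw_lognormal(mean: float, log_sd: float, rng: np.random.Generator, size=None):
    mu = np.log(mean) - log_sd**2 / 2.0
    return rng.lognormal(mu, log_sd, size=size)


def _split_cds(cds_len: int, n_introns: int, rng: np.random.Generator) -> list[int]:
    """Uniform random split of the CDS into n_introns+1 exons of >= MIN_EXON bp."""
    n_exons = n_introns + 1
    if n_exons == 1:
        return [cds_len]
    if cds_len < n_exons * MIN_EXON:
        raise ValueError("CDS too short for requested intron count")
    for _ in range(200):
        cuts = np.sort(rng.integers(MIN_EXON, cds_len - MIN_EXON + 1, size=n_introns))
        lens = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (lens >= MIN_EXON).all() and len(set(cuts.tolist())) == n_introns:
            return lens.tolist()
    # degenerate fallback: near-even split
    base = cds_len // n_exons
    lens = [base] * n_exons
    lens[-1] += cds_len - base * n_exons
    return lens


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_genome(
    spec: GenomeSpec, truth_config: TruthConfig | None = None
) -> SyntheticGenome:
    """Generate a genome (one contig per gene), its annotation, and planted truth.

    Deterministic given ``spec.seed``. With ``intron_density == 0`` every gene
    is mono-exonic and the truth table carries no exon entries (a warning-level
    degenerate case, not a failure).
    """
    tc = truth_config or TruthConfig()
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    exon_rows, intron_rows, gene_rows = [], [], []

    for g in range(spec.n_genes):
        gid = f"g{g:05d}"
        contig = f"ctg{g:05d}"
        cds_len = max(150, int(round(_draw_lognormal(spec.cds_len_mean, spec.cds_len_log_sd, rng))))
        n_introns = int(rng.poisson(spec.intron_density))
        max_introns = cds_len // MIN_EXON - 1
        n_introns = min(n_introns, max_introns)
        exon_lens = _split_cds(cds_len, n_introns, rng)
        intron_lens = [
            max(MIN_INTRON, int(round(x)))
            for x in np.atleast_1d(_draw_lognormal(spec.intron_len_mean, spec.intron_len_log_sd, rng, n_introns))
        ] if n_introns else []

        # build pre-mRNA in transcript orientation
        seg_arrays: list[np.ndarray] = []
        for i, el in enumerate(exon_lens):
            exon = _random_seq(el, spec.gc_exon, rng)
            if i > 0 and el >= MIN_EXON:
                exon[: len(THREE_PRIME_EXON)] = _noisy(THREE_PRIME_EXON, spec.ss_noise, rng)[: el]
            if i < n_introns and el >= MIN_EXON:
                tail = _noisy(FIVE_PRIME_EXON, spec.ss_noise, rng)
                exon[-len(tail):] = tail[-min(len(tail), el):]
            seg_arrays.append(exon)
            if i < n_introns:
                il = intron_lens[i]
                intron = _random_seq(il, spec.gc_intron, rng)
                intron[: len(FIVE_PRIME_INTRON)] = _noisy(FIVE_PRIME_INTRON, spec.ss_noise, rng)
                intron[-len(THREE_PRIME_INTRON):] = _noisy(THREE_PRIME_INTRON, spec.ss_noise, rng)
                seg_arrays.append(intron)
        premrna = b"".join(a.tobytes() for a in seg_arrays).decode()

        strand = "+" if rng.random() < 0.5 else "-"
        flank5 = _random_seq(spec.flank, 0.5, rng).tobytes().decode()
        flank3 = _random_seq(spec.flank, 0.5, rng).tobytes().decode()
        forward = flank5 + premrna + flank3
        contig_seq = forward if strand == "+" else revcomp(forward)
        L = len(contig_seq)

        # exon coordinates: transcript offsets -> genomic
        offsets = np.concatenate([[0], np.cumsum([len(a) for a in seg_arrays])])
        exon_ivs = []
        seg_i = 0
        for i in range(len(exon_lens)):
            a, b = offsets[seg_i], offsets[seg_i + 1]
            if strand == "+":
                exon_ivs.append((spec.flank + int(a), spec.flank + int(b)))
            else:
                exon_ivs.append((L - spec.flank - int(b), L - spec.flank - int(a)))
            seg_i += 2
        genome[contig] = contig_seq
        models[gid] = GeneModel(gid, gid + ".t1", contig, strand, tuple(sorted(exon_ivs)))

        # planted truth (indices are transcript order)
        n_exons = len(exon_lens)
        psi = np.zeros(n_exons)
        ret = np.zeros(n_introns)
        internal = list(range(1, n_exons - 1))
        if tc.mode == "independent":
            if internal:
                psi[internal] = rng.choice(tc.skip_choices, size=len(internal))
            if n_introns:
                ret[:] = rng.choice(tc.retention_choices, size=n_introns)
        elif tc.mode == "coupled":
            b0, b1, b2, b3 = tc.coupling_beta
            for e in internal:
                psi[e] = _sigmoid(
                    b0
                    + b1 * np.log(exon_lens[e])
                    + b2 * np.log(intron_lens[e - 1])
                    + b3 * np.log(intron_lens[e])
                )
            if n_introns:
                ret[:] = rng.choice(tc.retention_choices, size=n_introns)
        else:  # isolated: at most one event per gene
            want_es = rng.random() < 0.5
            if want_es and internal:
                psi[rng.choice(internal)] = rng.choice(tc.skip_choices)
            elif n_introns:
                ret[rng.integers(n_introns)] = rng.choice(tc.retention_choices)
        for e in internal:
            exon_rows.append((gid, e, float(psi[e])))
        for i in range(n_introns):
            intron_rows.append((gid, i, float(ret[i])))
        gene_rows.append((gid, float(_draw_lognormal(1.0, spec.expression_log_sd, rng))))

    truth = AsTruth(
        exons=pd.DataFrame(exon_rows, columns=["gene_id", "exon_index", "psi"]),
        introns=pd.DataFrame(intron_rows, columns=["gene_id", "intron_index", "retention"]),
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "expression"]),
    )
    return SyntheticGenome(spec=spec, genome=genome, models=models, truth=truth)


def simulate_reads(
    models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    truth: AsTruth,
    total_reads: int,
    read_len: int = 50,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample ``total_reads`` single-end reads from the isoform mixture.

    Reads are exact substrings of realized isoform sequences (no error model).
    Genes receive reads multinomially, proportional to expression weight times
    sampleable pre-mRNA positions.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(seed)
    gids = sorted(models)
    prepared = []
    weights = []
    for gid in gids:
        m = models[gid]
        segs = m.segments(genome)
        seg_lens = np.array([len(s) for s in segs])
        L_max = int(seg_lens.sum())
        if L_max < read_len:
            continue
        n_ex = m.n_exons
        psi = np.zeros(n_ex)
        for e in range(1, n_ex - 1):
            psi[e] = truth.psi(gid, e)
        ret = np.array([truth.retention(gid, i) for i in range(m.n_introns)], dtype=float)
        prepared.append((gid, segs, seg_lens, psi, ret, L_max))
        weights.append(truth.expression(gid) * (L_max - read_len + 1))
    if not prepared:
        raise ValueError("no gene long enough for the requested read length")
    w = np.array(weights, dtype=float)
    counts = rng.multinomial(total_reads, w / w.sum())

    reads: list[tuple[str, str]] = []
    rix = 0
    for (gid, segs, seg_lens, psi, ret, L_max), n_g in zip(prepared, counts):
        if n_g == 0:
            continue
        n_ex = len(psi)
        n_in = len(ret)
        exon_lens = seg_lens[0::2]
        intron_lens = seg_lens[1::2]
        iso_cache: dict[bytes, str] = {}
        need = int(n_g)
        while need > 0:
            batch = max(2 * need, 64)
            skip = rng.random((batch, n_ex)) < psi[None, :]
            kept_ex = ~skip
            if n_in:
                retained = rng.random((batch, n_in)) < ret[None, :]
                kept_in = retained & kept_ex[:, :-1] & kept_ex[:, 1:]
            else:
                kept_in = np.zeros((batch, 0), dtype=bool)
            L_r = kept_ex @ exon_lens + (kept_in @ intron_lens if n_in else 0)
            starts = rng.integers(0, L_max - read_len + 1, size=batch)
            ok = np.flatnonzero(starts <= L_r - read_len)[:need]
            for row in ok:
                flags = np.empty(len(segs), dtype=bool)
                flags[0::2] = kept_ex[row]
                if n_in:
                    flags[1::2] = kept_in[row]
                key = np.packbits(flags).tobytes()
                iso = iso_cache.get(key)
                if iso is None:
                    iso = "".join(s for s, k in zip(segs, flags) if k)
                    iso_cache[key] = iso
                s = int(starts[row])
                reads.append((f"{gid}|r{rix}", iso[s : s + read_len]))
                rix += 1
            need -= len(ok)
    return reads
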