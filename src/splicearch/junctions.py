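"""Exon-triplet (ES) and intron-triad (IR) junction composites.

A junction composite concatenates up to ``flank`` (default 42) nt from the 3'
end of the upstream element with up to ``flank`` nt from the 5' start of the
downstream element, in transcript orientation — the splice-site-adjacent
termini, so a 50-bp read can span the boundary. With both flanks at full
length a composite is 84 bp; shorter elements contribute their entire length.

ES: each internal exon E2 of a triplet (E1, E2, E3) is diagnosed by two
inclusion junctions (E1–E2, E2–E3) and one skip junction (E1–E3). Inclusion
junctions sit on exon boundaries and are shared by adjacent triplets; they are
stored once and referenced, so identical composites never compete with each
other during mapping.

IR: each intron is diagnosed by two retention junctions (E–I, I–E) and one
spliced junction (E–E). ES and IR junctions form separate libraries — they
are mapped in separate passes, as E–E junctions duplicate inclusion junctions
at the sequence level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .genemodel import GeneModel

DEFAULT_FLANK = 42


@dataclass(frozen=True)
class Junction:
    jid: str
    gene_id: str
    kind: str  # 'incl' | 'skip' | 'ei' | 'ie' | 'ee'
    up_len: int  # flank taken from the upstream element
    down_len: int
    seq: str


@dataclass(frozen=True)
class EsTriplet:
    gene_id: str
    e1: int
    e2: int
    e3: int
    j_incl1: str  # E1–E2
    j_incl2: str  # E2–E3
    j_skip: str  # E1–E3
    middle_len: int

    @property
    def is_3n(self) -> bool:
        return self.middle_len % 3 == 0

    @property
    def junction_ids(self) -> tuple[str, str, str]:
        return (self.j_incl1, self.j_incl2, self.j_skip)


@dataclass(frozen=True)
class IrTriad:
    gene_id: str
    intron_index: int
    j_ei: str
    j_ie: str
    j_ee: str
    intron_len: int

    @property
    def is_3n(self) -> bool:
        return self.intron_len % 3 == 0

    @property
    def junction_ids(self) -> tuple[str, str, str]:
        return (self.j_ei, self.j_ie, self.j_ee)


def _composite(up: str, down: str, flank: int) -> tuple[str, int, int]:
    u = min(flank, len(up))
    d = min(flank, len(down))
    return up[len(up) - u :] + down[:d], u, d


def build_es_junctions(
    model: GeneModel, genome: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> tuple[dict[str, Junction], list[EsTriplet]]:
    """All ES triplets of one gene (requires >= 3 exons; else empty)."""
    junctions: dict[str, Junction] = {}
    triplets: list[EsTriplet] = []
    if model.n_exons < 3:
        return junctions, triplets
    exons = model.exon_seqs(genome)
    gid = model.gene_id

    def boundary(b: int) -> str:
        jid = f"{gid}|EE{b}"
        if jid not in junctions:
            seq, u, d = _composite(exons[b], exons[b + 1], flank)
            junctions[jid] = Junction(jid, gid, "incl", u, d, seq)
        return jid

    for e2 in range(1, model.n_exons - 1):
        e1, e3 = e2 - 1, e2 + 1
        j1 = boundary(e1)
        j2 = boundary(e2)
        sk = f"{gid}|SK{e2}"
        seq, u, d = _composite(exons[e1], exons[e3], flank)
        junctions[sk] = Junction(sk, gid, "skip", u, d, seq)
        triplets.append(EsTriplet(gid, e1, e2, e3, j1, j2, sk, len(exons[e2])))
    return junctions, triplets


def build_ir_junctions(
    model: GeneModel, genome: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> tuple[dict[str, Junction], list[IrTriad]]:
    """All IR triads of one gene (one per intron, terminal introns included)."""
    junctions: dict[str, Junction] = {}
    triads: list[IrTriad] = []
    if model.n_introns == 0:
        return junctions, triads
    exons = model.exon_seqs(genome)
    introns = model.intron_seqs(genome)
    gid = model.gene_id
    for i, intron in enumerate(introns):
        jei, jie, jee = f"{gid}|EI{i}", f"{gid}|IE{i}", f"{gid}|EEi{i}"
        for jid, up, down, kind in (
            (jei, exons[i], intron, "ei"),
            (jie, intron, exons[i + 1], "ie"),
            (jee, exons[i], exons[i + 1], "ee"),
        ):
            seq, u, d = _composite(up, down, flank)
            junctions[jid] = Junction(jid, gid, kind, u, d, seq)
        triads.append(IrTriad(gid, i, jei, jie, jee, len(intron)))
    return junctions, triads


@dataclass
class JunctionLibrary:
    """One mapping target set: junction records plus the event composites
    that reference them."""

    junctions: dict[str, Junction]
    es_triplets: list[EsTriplet]
    ir_triads: list[IrTriad]

    @property
    def sequences(self) -> dict[str, str]:
        return {jid: j.seq for jid, j in self.junctions.items()}

    def flanks(self) -> dict[str, tuple[int, int]]:
        return {jid: (j.up_len, j.down_len) for jid, j in self.junctions.items()}

    def manifest(self) -> pd.DataFrame:
        rows = [
            (j.jid, j.gene_id, j.kind, j.up_len, j.down_len, len(j.seq))
            for j in self.junctions.values()
        ]
        return pd.DataFrame(
            rows, columns=["jid", "gene_id", "kind", "up_len", "down_len", "length"]
        )


def build_es_library(
    models: Mapping[str, GeneModel], genome: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> JunctionLibrary:
    junctions: dict[str, Junction] = {}
    triplets: list[EsTriplet] = []
    for gid in sorted(models):
        j, t = build_es_junctions(models[gid], genome, flank)
        junctions.update(j)
        triplets.extend(t)
    return JunctionLibrary(junctions, triplets, [])


def build_ir_library(
    models: Mapping[str, GeneModel], genome: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> JunctionLibrary:
    junctions: dict[str, Junction] = {}
    triads: list[IrTriad] = []
    for gid in sorted(models):
        j, t = build_ir_junctions(models[gid], genome, flank)
        junctions.update(j)
        triads.extend(t)
    return JunctionLibrary(junctions, [], triads)
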