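"""Gene models and canonical-transcript selection.

A :class:`GeneModel` is one transcript per gene, with exons stored in genomic
coordinates (0-based, half-open) but always iterated in *transcript* order
(5'→3' of the mRNA), so every downstream consumer — junction construction,
feature extraction, read simulation — is strand-agnostic.

Canonical-transcript selection keeps, for each gene, the isoform with the
longest total CDS; ties are broken by annotation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils

from .io import revcomp

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """One (canonical) transcript of one gene.

    ``exons`` are genomic intervals sorted by genomic start. Transcript-order
    accessors reverse them for minus-strand genes.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            object.__setattr__(self, "exons", tuple(sorted(self.exons)))

    # -- structure -----------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Genomic intron intervals (sorted by genomic start)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def _tx_order(self, intervals: tuple[Interval, ...]) -> tuple[Interval, ...]:
        return intervals if self.strand == "+" else intervals[::-1]

    @property
    def exons_tx(self) -> tuple[Interval, ...]:
        """Exons in transcript (5'→3') order."""
        return self._tx_order(self.exons)

    @property
    def introns_tx(self) -> tuple[Interval, ...]:
        return self._tx_order(self.introns)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons_tx]

    def intron_lengths(self) -> list[int]:
        return [e - s for s, e in self.introns_tx]

    # -- sequence ------------------------------------------------------
    def _fetch(self, genome: Mapping[str, str], iv: Interval) -> str:
        seq = genome[self.contig][iv[0] : iv[1]]
        return seq if self.strand == "+" else revcomp(seq)

    def exon_seqs(self, genome: Mapping[str, str]) -> list[str]:
        return [self._fetch(genome, iv) for iv in self.exons_tx]

    def intron_seqs(self, genome: Mapping[str, str]) -> list[str]:
        return [self._fetch(genome, iv) for iv in self.introns_tx]

    def transcript_seq(self, genome: Mapping[str, str]) -> str:
        return "".join(self.exon_seqs(genome))

    def premrna_seq(self, genome: Mapping[str, str]) -> str:
        """Exons and introns interleaved, transcript orientation."""
        ex, intr = self.exon_seqs(genome), self.intron_seqs(genome)
        parts = []
        for i, e in enumerate(ex):
            parts.append(e)
            if i < len(intr):
                parts.append(intr[i])
        return "".join(parts)

    def segments(self, genome: Mapping[str, str]) -> list[str]:
        """[E0, I0, E1, I1, ..., En] sequences in transcript orientation."""
        ex, intr = self.exon_seqs(genome), self.intron_seqs(genome)
        out = []
        for i, e in enumerate(ex):
            out.append(e)
            if i < len(intr):
                out.append(intr[i])
        return out

    def event_position(self, index: int, kind: str) -> int:
        """bp offset from the start codon (pre-mRNA coords) of exon/intron ``index``."""
        ex, intr = self.exon_lengths(), self.intron_lengths()
        pos = 0
        if kind == "exon":
            for i in range(index):
                pos += ex[i]
                pos += intr[i]
            return pos
        if kind == "intron":
            for i in range(index + 1):
                pos += ex[i]
                if i < index:
                    pos += intr[i]
            return pos
        raise ValueError(kind)


def extract_canonical_models(
    gff: str | Path | gffutils.FeatureDB, genome: Mapping[str, str] | None = None
) -> dict[str, GeneModel]:
    """Pick one transcript per gene: the one with the longest summed CDS.

    Genes whose transcripts carry no CDS are skipped with a log entry.
    Ties on CDS length are broken by annotation order.
    """
    if isinstance(gff, gffutils.FeatureDB):
        db = gff
    else:
        db = gffutils.create_db(
            str(gff),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        best = None  # (cds_len, order, mrna)
        for order, mrna in enumerate(db.children(gene, featuretype="mRNA", order_by="start")):
            cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
            if cds_len == 0:
                continue
            if best is None or cds_len > best[0]:
                best = (cds_len, order, mrna)
        if best is None:
            logger.info("gene %s has no CDS-bearing transcript; skipped", gene.id)
            continue
        mrna = best[2]
        exons = tuple(
            sorted(
                (e.start - 1, e.end)  # GFF3 1-based inclusive -> 0-based half-open
                for e in db.children(mrna, featuretype="exon")
            )
        )
        if not exons:
            exons = tuple(
                sorted((c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS"))
            )
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            transcript_id=mrna.id,
            contig=gene.seqid,
            strand=gene.strand,
            exons=exons,
        )
    return models
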