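"""Thin wrappers around standard sequence formats.

FASTA/FASTQ go through Biopython; GFF3 writing is done here because the
synthetic annotations are simple (gene > mRNA > exon/CDS, no UTRs) and the
writer must be byte-deterministic for the seed-reproducibility contract.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{name: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs with a constant quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def iter_fastq_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def fasta_string(seqs: dict[str, str], width: int = 70) -> str:
    buf = _io.StringIO()
    for name, seq in seqs.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


def as_seqrecords(seqs: dict[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
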