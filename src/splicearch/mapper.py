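"""Unique read-to-junction assignment and effective mappability.

The junction library is tiny (tens of thousands of ≤84-bp sequences), so an
exact exhaustive matcher replaces a heuristic genome aligner: a read is
aligned end-to-end against every 50-bp window of every junction, allowing up
to two mismatches (Hamming; no indels), in both orientations of the read.
A read is assigned only if exactly one (junction, offset, orientation) aligns
— multi-mapping reads are discarded entirely.

Candidate windows are found by the pigeonhole principle: a read within two
mismatches of a window must match it exactly in at least one of three
read-length/3 segments, so three hash lookups bound the candidate set, after
which alignments are verified exactly. This is exact, not heuristic.

Effective mappability of a junction counts its windows that map uniquely back
to their own position; the ceiling is 35 for 84-bp junctions and 50-bp reads.
A junction passes the filter if >= 20 windows are effective and at least 8
effective windows overlap each side of the boundary by >= 8 bp; event
composites (triplets/triads) are dropped whole if any member junction fails.
Windows containing uncalled bases (N) are non-mappable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import revcomp

DEFAULT_READ_LEN = 50
DEFAULT_MAX_MISMATCHES = 2
MAPPABILITY_FLOOR = 20
PER_SIDE_FLOOR = 8
SIDE_OVERLAP = 8
MAX_WINDOWS = 35  # 84 - 50 + 1


def enumerate_windows(seq: str, read_len: int = DEFAULT_READ_LEN) -> list[str]:
    """All read-length substrings of a junction; empty if it is too short."""
    if len(seq) < read_len:
        return []
    return [seq[i : i + read_len] for i in range(len(seq) - read_len + 1)]


def _parts(read_len: int, n: int) -> list[tuple[int, int]]:
    cut = np.linspace(0, read_len, n + 1).astype(int)
    return [(int(cut[i]), int(cut[i + 1])) for i in range(n)]


@dataclass(frozen=True)
class MappabilityRecord:
    jid: str
    n_possible: int
    n_effective: int
    eff_up: int  # effective windows overlapping the upstream side by >= 8 bp
    eff_down: int
    passed: bool


class JunctionIndex:
    """Exact ≤``max_mismatches`` unique matcher over a junction library."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        read_len: int = DEFAULT_READ_LEN,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        both_strands: bool = True,
    ):
        if not sequences:
            raise ValueError("empty junction library")
        self.read_len = read_len
        self.max_mismatches = max_mismatches
        self.both_strands = both_strands
        self.jids: list[str] = sorted(sequences)
        self._win_seq: list[str] = []
        self._win_jid: list[int] = []
        self._win_off: list[int] = []
        for ji, jid in enumerate(self.jids):
            for off, w in enumerate(enumerate_windows(sequences[jid], read_len)):
                self._win_seq.append(w)
                self._win_jid.append(ji)
                self._win_off.append(off)
        self._bounds = _parts(read_len, max_mismatches + 1)
        self._seed_maps: list[dict[str, list[int]]] = []
        for a, b in self._bounds:
            d: dict[str, list[int]] = {}
            for wi, w in enumerate(self._win_seq):
                d.setdefault(w[a:b], []).append(wi)
            self._seed_maps.append(d)

    # -- core ----------------------------------------------------------
    def _candidates(self, read: str) -> set[int]:
        cand: set[int] = set()
        for (a, b), smap in zip(self._bounds, self._seed_maps):
            hits = smap.get(read[a:b])
            if hits:
                cand.update(hits)
        return cand

    def alignments(self, read: str) -> list[tuple[str, int, str, int]]:
        """All (jid, offset, strand, mismatches) with mm <= max_mismatches."""
        if len(read) != self.read_len:
            return []
        out = []
        queries = [(read, "+")]
        if self.both_strands:
            queries.append((revcomp(read), "-"))
        mm_max = self.max_mismatches
        for q, strand in queries:
            for wi in self._candidates(q):
                w = self._win_seq[wi]
                mm = 0
                for x, y in zip(q, w):
                    if x != y:
                        mm += 1
                        if mm > mm_max:
                            break
                else:
                    out.append((self.jids[self._win_jid[wi]], self._win_off[wi], strand, mm))
        return out

    def assign(self, read: str) -> str | None:
        """Unique-mapping contract: exactly one alignment, else unassigned."""
        al = self.alignments(read)
        return al[0][0] if len(al) == 1 else None

    def map_reads(
        self, reads: Iterable[str | tuple[str, str]]
    ) -> tuple[Counter, dict[str, int]]:
        """Assign reads; returns per-junction raw counts and filter tallies."""
        counts: Counter = Counter()
        stats = {"input": 0, "assigned": 0, "multimapped": 0, "unmapped": 0}
        for r in reads:
            seq = r[1] if isinstance(r, tuple) else r
            stats["input"] += 1
            al = self.alignments(seq)
            if len(al) == 1:
                counts[al[0][0]] += 1
                stats["assigned"] += 1
            elif len(al) > 1:
                stats["multimapped"] += 1
            else:
                stats["unmapped"] += 1
        return counts, stats

    # -- mappability ---------------------------------------------------
    def effective_mappability(
        self, flanks: Mapping[str, tuple[int, int]]
    ) -> pd.DataFrame:
        """Per-junction effective mappability and the pass flag.

        ``flanks`` maps jid -> (upstream flank length, downstream flank
        length) as recorded by the junction builder.
        """
        jid_windows: dict[str, list[tuple[int, str]]] = {j: [] for j in self.jids}
        for wi, w in enumerate(self._win_seq):
            jid_windows[self.jids[self._win_jid[wi]]].append((self._win_off[wi], w))
        rows = []
        for jid in self.jids:
            up, _down = flanks[jid]
            wins = jid_windows[jid]
            n_possible = len(wins)
            n_eff = eff_up = eff_down = 0
            for off, w in wins:
                if "N" in w:
                    continue  # uncalled bases: non-mappable window
                if len(self.alignments(w)) == 1:
                    n_eff += 1
                    up_overlap = up - off
                    down_overlap = self.read_len - up_overlap
                    if up_overlap >= SIDE_OVERLAP:
                        eff_up += 1
                    if down_overlap >= SIDE_OVERLAP:
                        eff_down += 1
            passed = (
                n_eff >= MAPPABILITY_FLOOR
                and eff_up >= PER_SIDE_FLOOR
                and eff_down >= PER_SIDE_FLOOR
            )
            rows.append((jid, n_possible, n_eff, eff_up, eff_down, passed))
        return pd.DataFrame(
            rows,
            columns=["jid", "n_possible", "n_effective", "eff_up", "eff_down", "passed"],
        ).set_index("jid")


def effective_mappability(
    library_sequences: Mapping[str, str],
    flanks: Mapping[str, tuple[int, int]],
    read_len: int = DEFAULT_READ_LEN,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: build the index and score every junction."""
    idx = JunctionIndex(library_sequences, read_len, max_mismatches, both_strands)
    return idx.effective_mappability(flanks)


def map_unique(
    reads: Sequence[str],
    library_sequences: Mapping[str, str],
    read_len: int = DEFAULT_READ_LEN,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    both_strands: bool = True,
) -> list[str | None]:
    """Per-read unique assignment (jid or None), functional form."""
    idx = JunctionIndex(library_sequences, read_len, max_mismatches, both_strands)
    return [idx.assign(r) for r in reads]


def triplet_pass(
    events: Iterable, mappability: pd.DataFrame
) -> dict[tuple, bool]:
    """Whole-composite filter: an event passes iff all three junctions pass."""
    passed = mappability["passed"]
    out = {}
    for ev in events:
        out[_event_key(ev)] = all(bool(passed.get(j, False)) for j in ev.junction_ids)
    return out


def _event_key(ev) -> tuple:
    if hasattr(ev, "e2"):
        return (ev.gene_id, "es", ev.e2)
    return (ev.gene_id, "ir", ev.intron_index)


def qc_filter_report(
    library,
    mappability: pd.DataFrame,
    min_side: int = 27,
) -> pd.DataFrame:
    """Filter-survival accounting, one row per filter stage.

    Stages mirror the pipeline QC: junction length (both flanks long enough
    to leave >= 20 windows), uncalled bases, and the effective-mappability
    filter (which folds in multi-mapping and mismatch removals).
    """
    juncs = list(library.junctions.values())
    n_total = len(juncs)
    length_ok = [j for j in juncs if min(j.up_len, j.down_len) >= min_side]
    no_n = [j for j in length_ok if "N" not in j.seq]
    passed = [j for j in no_n if bool(mappability.loc[j.jid, "passed"])]
    rows = [
        ("all_junctions", n_total, 1.0),
        ("length_ge_%d_each_side" % min_side, len(length_ok), len(length_ok) / n_total if n_total else 0.0),
        ("no_uncalled_bases", len(no_n), len(no_n) / n_total if n_total else 0.0),
        ("effective_mappability", len(passed), len(passed) / n_total if n_total else 0.0),
    ]
    return pd.DataFrame(rows, columns=["filter", "surviving", "fraction_of_total"])
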