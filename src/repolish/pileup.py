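"""Pileup construction over mapped reads.

Counts are held in per-sequence numpy arrays (rows A, C, G, T, N, deletion);
insertion and deletion events are left-normalized against the reference so
that homopolymer-length evidence from reads entering a run at different
offsets accumulates at a single locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .mapping import MappedRead
from .model import Assembly

_BASE_IDX = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _BASE_IDX[ord(_b)] = _i
ROW_A, ROW_C, ROW_G, ROW_T, ROW_N, ROW_DEL = range(6)


@dataclass
class PileupColumn:
    seq_id: str
    pos: int
    base_counts: dict[str, int]  # A C G T N and '-' for deletion
    insertion_events: Counter

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


def _left_normalize(ref: str, pos: int, allele: str) -> tuple[int, str]:
    """Shift an indel event left through repeated sequence (VCF-style)."""
    while pos > 0 and allele and allele[-1] == ref[pos - 1]:
        allele = ref[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


class Pileup:
    """Per-position base counts plus indel events for one assembly."""

    def __init__(self, ref: Assembly, min_base_q: int = 20):
        self.min_base_q = min_base_q
        self.refs = {s.id: s.residues for s in ref.sequences()}
        self.counts = {
            sid: np.zeros((6, len(res)), dtype=np.int32) for sid, res in self.refs.items()
        }
        # insertion of `seq` before ref position `pos`
        self.insertions: dict[str, Counter] = {sid: Counter() for sid in self.refs}
        # deletion of ref[a:b]
        self.deletions: dict[str, Counter] = {sid: Counter() for sid in self.refs}
        self._spans: dict[str, list[tuple[int, int]]] = {sid: [] for sid in self.refs}
        self._span_arr: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def add_read(self, m: MappedRead) -> None:
        counts = self.counts[m.seq_id]
        ref = self.refs[m.seq_id]
        quals = np.frombuffer(m.qual.encode(), dtype=np.uint8).astype(np.int16) - 33
        seq_idx = _BASE_IDX[np.frombuffer(m.seq.encode(), dtype=np.uint8)]
        rp, gp = 0, m.start
        for op, n in m.cigar:
            if op in "=XM":
                ok = quals[rp : rp + n] >= self.min_base_q
                pos = np.arange(gp, gp + n)[ok]
                np.add.at(counts, (seq_idx[rp : rp + n][ok], pos), 1)
                rp += n
                gp += n
            elif op == "I":
                pos, allele = _left_normalize(ref, gp, m.seq[rp : rp + n])
                self.insertions[m.seq_id][(pos, allele)] += 1
                rp += n
            else:  # D
                a, _ = _left_normalize(ref, gp, ref[gp : gp + n])
                counts[ROW_DEL, a : a + n] += 1
                self.deletions[m.seq_id][(a, a + n)] += 1
                gp += n
        self._spans[m.seq_id].append((m.start, gp))
        self._span_arr.pop(m.seq_id, None)

    def spanning_depth(self, seq_id: str, a: int, b: int) -> int:
        """Number of reads whose alignment fully covers [a, b)."""
        if seq_id not in self._span_arr:
            spans = self._spans[seq_id]
            starts = np.array([s for s, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e in spans], dtype=np.int64)
            self._span_arr[seq_id] = (starts, ends)
        starts, ends = self._span_arr[seq_id]
        if len(starts) == 0:
            return 0
        return int(np.sum((starts <= a) & (ends >= b)))

    def column(self, seq_id: str, pos: int) -> PileupColumn:
        c = self.counts[seq_id][:, pos]
        ins = Counter(
            {allele: n for (p, allele), n in self.insertions[seq_id].items() if p == pos}
        )
        return PileupColumn(
            seq_id,
            pos,
            {"A": int(c[0]), "C": int(c[1]), "G": int(c[2]), "T": int(c[3]),
             "N": int(c[4]), "-": int(c[5])},
            ins,
        )

    def covered_positions(self, seq_id: str) -> np.ndarray:
        return np.flatnonzero(self.counts[seq_id].sum(axis=0) > 0)


def build_pileup(
    mapped: list[MappedRead], ref: Assembly, min_base_q: int = 20
) -> Pileup:
    """Build a pileup from position-sorted mapped reads.

    Bases with quality below ``min_base_q`` are excluded from substitution
    counts (the mpileup-style quality floor); indel events are not quality
    filtered but require spanning support downstream.
    """
    pile = Pileup(ref, min_base_q=min_base_q)
    for m in mapped:
        pile.add_read(m)
    return pile
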