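"""Paired-end read mapping against an assembly.

A k-mer seeded, edlib-verified mapper sized for the desk-scale inputs this
package targets (regions up to a few Mb). Seeds vote on diagonals, candidate
loci are verified by infix alignment, and mates are placed jointly using the
library's insert bounds. Reads whose best placement is tied between distinct
loci are left unplaced and counted as ambiguous — repeat-derived reads must
not vote in downstream consensus steps.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib

from .model import Assembly, ReadPairSet, revcomp

_CIG = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG.findall(cigar)]


@dataclass
class MappedRead:
    """One placed read with its alignment path against the reference.

    ``seq``/``qual`` are stored in reference orientation (reverse-complemented
    for '-' strand placements). The cigar uses ``= X I D`` where I is a read
    base absent from the reference and D a reference base absent from the read.
    """

    read_id: str
    seq_id: str
    start: int
    strand: str
    cigar: list[tuple[str, int]]
    edits: int
    seq: str
    qual: str
    pair_index: int = -1
    mate: int = 0  # 1 or 2

    @property
    def ref_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in "=XDM")

    def aligned_pairs(self):
        """Yield (read_pos, ref_pos) with None on the gapped side."""
        rp, gp = 0, self.start
        for op, n in self.cigar:
            if op in "=XM":
                for _ in range(n):
                    yield rp, gp
                    rp += 1
                    gp += 1
            elif op == "I":
                for _ in range(n):
                    yield rp, None
                    rp += 1
            else:  # D
                for _ in range(n):
                    yield None, gp
                    gp += 1


@dataclass
class MappingResult:
    placed: list[MappedRead]
    n_reads: int
    n_ambiguous: int
    n_unplaced: int

    @property
    def unplaced_fraction(self) -> float:
        return (self.n_unplaced + self.n_ambiguous) / self.n_reads if self.n_reads else 0.0


class RefIndex:
    """Exact k-mer index over all assembly sequences (N-containing k-mers skipped)."""

    def __init__(self, ref: Assembly, k: int = 21, max_occ: int = 64):
        self.k = k
        self.seqs: list[tuple[str, str]] = [(s.id, s.residues) for s in ref.sequences()]
        index: dict[str, list[tuple[int, int]]] = {}
        for si, (_, residues) in enumerate(self.seqs):
            for pos in range(0, len(residues) - k + 1):
                kmer = residues[pos : pos + k]
                if "N" in kmer:
                    continue
                hits = index.setdefault(kmer, [])
                if len(hits) < max_occ:
                    hits.append((si, pos))
        self.index = index

    def seed_candidates(self, seq: str, stride: int = 12, band: int = 24):
        """Candidate (seq_idx, approx_diagonal) loci by banded seed voting."""
        k = self.k
        votes: Counter = Counter()
        last = len(seq) - k
        if last < 0:
            return []
        positions = list(range(0, last, stride)) + [last]
        for rp in positions:
            for si, tp in self.index.get(seq[rp : rp + k], ()):
                votes[(si, (tp - rp) // band)] += 1
        if not votes:
            return []
        best = max(votes.values())
        thresh = max(1, best // 2)
        out = []
        seen = set()
        for (si, db), v in votes.most_common():
            if v < thresh:
                break
            if (si, db) in seen:
                continue
            # merge adjacent diagonal buckets
            seen.update({(si, db), (si, db - 1), (si, db + 1)})
            out.append((si, db * band))
        return out[:8]


@dataclass
class _Placement:
    seq_idx: int
    start: int
    strand: str
    edits: int
    cigar: list[tuple[str, int]]


def _verify(index: RefIndex, seq: str, si: int, diag: int, max_edits: int,
            pad: int = 40) -> _Placement | None:
    _, target = index.seqs[si]
    w0 = max(0, diag - pad)
    w1 = min(len(target), diag + len(seq) + pad)
    if w1 - w0 < len(seq) // 2:
        return None
    res = edlib.align(seq, target[w0:w1], mode="HW", task="path", k=max_edits)
    if res["editDistance"] < 0:
        return None
    loc = res["locations"][0]
    return _Placement(si, w0 + loc[0], "+", res["editDistance"], parse_cigar(res["cigar"]))


def _map_single(index: RefIndex, seq: str, max_edits: int) -> list[_Placement]:
    """Best placements of one read in both orientations (within 2 edits of best)."""
    placements: list[_Placement] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for si, diag in index.seed_candidates(s):
            p = _verify(index, s, si, diag, max_edits)
            if p is not None:
                p.strand = strand
                if not any(
                    q.seq_idx == p.seq_idx and abs(q.start - p.start) < 30
                    and q.strand == p.strand
                    for q in placements
                ):
                    placements.append(p)
    if not placements:
        return []
    best = min(p.edits for p in placements)
    return [p for p in placements if p.edits <= best + 2]


def _unique_best(placements: list[_Placement]) -> _Placement | None:
    """The strictly best placement, or None on a tie between distinct loci."""
    if not placements:
        return None
    best = min(p.edits for p in placements)
    tops = [p for p in placements if p.edits == best]
    if len(tops) > 1:
        return None
    return tops[0]


def map_reads(
    reads: ReadPairSet,
    ref: Assembly,
    max_mismatch_frac: float = 0.04,
    k: int = 21,
    index: RefIndex | None = None,
) -> MappingResult:
    """Map mated reads, preferring proper pairs within the insert bounds.

    Each mate is seeded and verified independently; when a proper-pair
    combination (opposite strands, innie orientation, insert within
    [insert_min, insert_max]) exists it is preferred, otherwise each mate is
    placed at its unique best locus. Ties between distinct loci leave the
    read unplaced (counted as ambiguous).
    """
    if index is None:
        index = RefIndex(ref, k=k)
    placed: list[MappedRead] = []
    n_ambiguous = 0
    n_unplaced = 0

    def emit(pi: int, mate: int, rid: str, raw_seq: str, raw_qual: str, p: _Placement):
        seq, qual = (raw_seq, raw_qual) if p.strand == "+" else (
            revcomp(raw_seq), raw_qual[::-1])
        placed.append(
            MappedRead(rid, index.seqs[p.seq_idx][0], p.start, p.strand,
                       p.cigar, p.edits, seq, qual, pi, mate)
        )

    imin, imax = reads.insert_min, reads.insert_max
    for pi, pair in enumerate(reads.pairs):
        me1 = int(max_mismatch_frac * len(pair.seq1))
        me2 = int(max_mismatch_frac * len(pair.seq2))
        pl1 = _map_single(index, pair.seq1, me1)
        pl2 = _map_single(index, pair.seq2, me2)
        proper: list[tuple[int, _Placement, _Placement]] = []
        for p1 in pl1:
            for p2 in pl2:
                if p1.seq_idx != p2.seq_idx or p1.strand == p2.strand:
                    continue
                fwd, rev = (p1, p2) if p1.strand == "+" else (p2, p1)
                rev_end = rev.start + sum(n for op, n in rev.cigar if op in "=XDM")
                insert = rev_end - fwd.start
                if fwd.start <= rev.start and imin <= insert <= imax:
                    proper.append((p1.edits + p2.edits, p1, p2))
        if proper:
            proper.sort(key=lambda t: t[0])
            if len(proper) > 1 and proper[0][0] == proper[1][0]:
                n_ambiguous += 2
                continue
            _, p1, p2 = proper[0]
            emit(pi, 1, f"{pair.id}/1", pair.seq1, pair.qual1, p1)
            emit(pi, 2, f"{pair.id}/2", pair.seq2, pair.qual2, p2)
            continue
        for mate, raw_seq, raw_qual, pls in (
            (1, pair.seq1, pair.qual1, pl1),
            (2, pair.seq2, pair.qual2, pl2),
        ):
            if not pls:
                n_unplaced += 1
                continue
            p = _unique_best(pls)
            if p is None:
                n_ambiguous += 1
            else:
                emit(pi, mate, f"{pair.id}/{mate}", raw_seq, raw_qual, p)
    placed.sort(key=lambda m: (m.seq_id, m.start))
    return MappingResult(placed, 2 * len(reads.pairs), n_ambiguous, n_unplaced)
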