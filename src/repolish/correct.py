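"""Iterative pileup-based consensus correction.

Reads are remapped to the working assembly each iteration; substitutions and
1-3 bp indel errors are corrected wherever a strict majority of reads
disagrees with the reference: more than 75% of covering reads supporting one
alternative at a depth of at least four. The strictness is deliberate — on a
doubled-haploid source every genuine disagreement should be near-unanimous,
and columns that look heterozygous (intermediate alternate fractions) are
mapping artifacts to be logged, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import MappingResult, RefIndex, map_reads
from .model import Assembly, ReadPairSet, Sequence
from .pileup import Pileup, PileupColumn, ROW_DEL, build_pileup

TABLE_CLASS_NAMES = {
    # correction kind -> corrected-error class it removes from the assembly
    "substitution": "1 bp substitution errors",
    "insertion_1_3": "1-3 bp deletion errors",
    "deletion_1_3": "1-3 bp insertion errors",
}


@dataclass
class CorrectionRecord:
    seq_id: str
    pos: int  # coordinate in the assembly version the iteration started from
    kind: str  # substitution | insertion_1_3 | deletion_1_3
    before: str
    after: str
    support_fraction: float
    depth: int
    iteration: int


@dataclass
class CorrectionLedger:
    records: list[CorrectionRecord] = field(default_factory=list)
    frozen: list[tuple[str, int]] = field(default_factory=list)
    het_like: int = 0  # columns with intermediate alt fractions, logged not corrected

    def of_iteration(self, it: int) -> list[CorrectionRecord]:
        return [r for r in self.records if r.iteration == it]

    def gross_counts(self) -> dict[str, int]:
        out = {k: 0 for k in TABLE_CLASS_NAMES.values()}
        for r in self.records:
            out[TABLE_CLASS_NAMES[r.kind]] += 1
        return out

    def net_counts(self) -> dict[str, int]:
        """Gross counts minus reverted pairs (a later record undoing an earlier one).

        The oscillation guard keeps reverts rare; both tallies are reported
        because whether published corrected-error counts include reverts is
        generally unknowable from the reports of the tools that produce them.
        """
        out = self.gross_counts()
        open_edits: dict[tuple[str, str, str], int] = {}
        for r in self.records:
            inv = (r.seq_id, r.after, r.before)
            key = (r.seq_id, r.before, r.after)
            if open_edits.get(inv, 0) > 0:
                open_edits[inv] -= 1
                out[TABLE_CLASS_NAMES[r.kind]] -= 2
            else:
                open_edits[key] = open_edits.get(key, 0) + 1
        return out

    def coordinate_maps(self):
        """Per-iteration coordinate maps of the indel corrections (for
        projecting pre-correction positions into the corrected assembly)."""
        from .coords import CoordinateMap

        maps = []
        for it in sorted({r.iteration for r in self.records}):
            m = CoordinateMap()
            for r in self.of_iteration(it):
                if r.kind == "insertion_1_3":
                    m.add(r.seq_id, r.pos, r.pos, len(r.after))
                elif r.kind == "deletion_1_3":
                    m.add(r.seq_id, r.pos, r.pos + len(r.before), 0)
            maps.append(m)
        return maps

    def apply(self, a: Assembly) -> Assembly:
        """Replay the ledger over the input assembly, iteration by iteration."""
        out = a.copy()
        iters = sorted({r.iteration for r in self.records})
        for it in iters:
            recs = sorted(self.of_iteration(it), key=lambda r: -r.pos)
            seqs = {s.id: s.residues for s in out.sequences()}
            for r in recs:
                s = seqs[r.seq_id]
                if r.kind == "substitution":
                    seqs[r.seq_id] = s[: r.pos] + r.after + s[r.pos + 1 :]
                elif r.kind == "insertion_1_3":
                    seqs[r.seq_id] = s[: r.pos] + r.after + s[r.pos :]
                else:
                    seqs[r.seq_id] = s[: r.pos] + s[r.pos + len(r.before) :]
            for s in out.sequences():
                s.residues = seqs[s.id]
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tpos\tkind\tclass\tbefore\tafter\tsupport\tdepth\titeration\n")
            for r in self.records:
                fh.write(
                    f"{r.seq_id}\t{r.pos}\t{r.kind}\t{TABLE_CLASS_NAMES[r.kind]}\t"
                    f"{r.before}\t{r.after}\t{r.support_fraction:.3f}\t{r.depth}\t{r.iteration}\n"
                )


def apply_majority_rule(
    col: PileupColumn, ref_base: str, min_frac: float = 0.75, min_depth: int = 4
) -> str:
    """Strict-majority substitution decision for one pileup column.

    Returns ``"keep"`` or ``"change-to-X"``. A change requires depth of at
    least ``min_depth`` and the top non-reference nucleotide to be supported
    by strictly more than ``min_frac`` of the column depth.
    """
    depth = col.depth
    if depth < min_depth:
        return "keep"
    alts = {b: n for b, n in col.base_counts.items() if b in "ACGT" and b != ref_base}
    if not alts:
        return "keep"
    top = max(alts, key=lambda b: (alts[b], b))
    if alts[top] / depth > min_frac:
        return f"change-to-{top}"
    return "keep"


_BASE_ROWS = {"A": 0, "C": 1, "G": 2, "T": 3}


def _substitution_changes(
    pile: Pileup, seq: Sequence, min_frac: float, min_depth: int
) -> tuple[list[tuple[int, str, str, float, int]], int]:
    """Vectorized scan for columns passing the strict-majority rule."""
    counts = pile.counts[seq.id]
    depth = counts.sum(axis=0)
    ref_idx = np.array([_BASE_ROWS.get(b, 4) for b in seq.residues], dtype=np.int8)
    acgt = counts[:4].copy()
    cols = np.arange(acgt.shape[1])
    valid = ref_idx < 4
    acgt[ref_idx[valid], cols[valid]] = 0  # mask the reference allele
    alt_counts = acgt.max(axis=0)
    alt_rows = acgt.argmax(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
    hits = np.flatnonzero((depth >= min_depth) & (frac > min_frac))
    het_like = int(np.sum((depth >= min_depth) & (frac >= 0.4) & (frac <= 0.6)))
    out = []
    for p in hits:
        out.append(
            (int(p), seq.residues[p], "ACGT"[alt_rows[p]], float(frac[p]), int(depth[p]))
        )
    return out, het_like


def _indel_changes(
    pile: Pileup, seq: Sequence, min_frac: float, min_depth: int, span_pad: int = 5
) -> list[tuple[int, str, str, str, float, int]]:
    """1-3 bp indel events passing the strict-majority rule over spanning reads."""
    out = []
    for (pos, allele), n in pile.insertions[seq.id].items():
        if not 1 <= len(allele) <= 3:
            continue
        spanning = pile.spanning_depth(seq.id, pos - span_pad, pos + span_pad)
        if spanning >= min_depth and n / spanning > min_frac:
            out.append((pos, "insertion_1_3", "", allele, n / spanning, spanning))
    for (a, b), n in pile.deletions[seq.id].items():
        if not 1 <= b - a <= 3:
            continue
        spanning = pile.spanning_depth(seq.id, a - span_pad, b + span_pad)
        if spanning >= min_depth and n / spanning > min_frac:
            out.append((a, "deletion_1_3", seq.residues[a:b], "", n / spanning, spanning))
    return out


def correct_consensus(
    ref: Assembly,
    reads: ReadPairSet,
    iterations: int = 4,
    min_frac: float = 0.75,
    min_depth: int = 4,
    min_base_q: int = 20,
    max_mismatch_frac: float = 0.04,
) -> tuple[Assembly, CorrectionLedger]:
    """Iteratively remap, pile up, and correct substitution and 1-3 bp indel errors.

    Stops early once an iteration makes no changes. Positions that a later
    iteration tries to revert are frozen and logged (oscillation guard).
    The ledger records every applied change with its supporting evidence;
    ``ledger.apply(input)`` reproduces the output.
    """
    current = ref.copy()
    ledger = CorrectionLedger()
    applied_signatures: set[tuple[str, str, str, str]] = set()

    for it in range(1, iterations + 1):
        mapres = map_reads(reads, current, max_mismatch_frac=max_mismatch_frac)
        pile = build_pileup(mapres.placed, current, min_base_q=min_base_q)
        iteration_records: list[CorrectionRecord] = []
        for seq in current.sequences():
            subs, het = _substitution_changes(pile, seq, min_frac, min_depth)
            ledger.het_like += het
            changes: list[tuple[int, str, str, str, float, int]] = [
                (p, "substitution", before, after, fr, d)
                for p, before, after, fr, d in subs
            ]
            changes += _indel_changes(pile, seq, min_frac, min_depth)
            changes.sort(key=lambda c: -c[0])
            occupied: set[int] = set()
            for pos, kind, before, after, frac, depth in changes:
                width = max(len(before), 1)
                if any(p in occupied for p in range(pos - 3, pos + width + 3)):
                    continue
                ctx = seq.residues[max(0, pos - 8) : pos + width + 8]
                sig = (seq.id, ctx, before, after)
                inv = (seq.id, ctx.replace(before, after, 1) if before else ctx,
                       after, before)
                if inv in applied_signatures:
                    ledger.frozen.append((seq.id, pos))
                    continue
                applied_signatures.add(sig)
                occupied.update(range(pos, pos + width))
                iteration_records.append(
                    CorrectionRecord(seq.id, pos, kind, before, after, frac, depth, it)
                )
        if not iteration_records:
            break
        # apply this iteration's records (descending positions keep coords valid)
        by_seq: dict[str, list[CorrectionRecord]] = {}
        for r in iteration_records:
            by_seq.setdefault(r.seq_id, []).append(r)
        for seq in current.sequences():
            recs = sorted(by_seq.get(seq.id, []), key=lambda r: -r.pos)
            s = seq.residues
            for r in recs:
                if r.kind == "substitution":
                    s = s[: r.pos] + r.after + s[r.pos + 1 :]
                elif r.kind == "insertion_1_3":
                    s = s[: r.pos] + r.after + s[r.pos :]
                else:
                    s = s[: r.pos] + s[r.pos + len(r.before) :]
            seq.residues = s
        ledger.records.extend(iteration_records)
    return current, ledger


def unmapped_fraction(reads: ReadPairSet, ref: Assembly,
                      max_mismatch_frac: float = 0.04) -> float:
    """Fraction of reads left unplaced when mapping against an assembly."""
    return map_reads(reads, ref, max_mismatch_frac=max_mismatch_frac).unplaced_fraction
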