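"""Gap refinement: anchored read extension, convention-gap merging, resizing.

Gaps (interior N-stretches) are closed by recruiting read pairs with one
mate anchored in a gap flank and the other dangling gap-ward, then greedily
extending each flank by k-mer consensus of the dangling mates. When the two
extensions overlap, the gap is spliced closed; otherwise the N-run shrinks
by the bases gained and the next iteration tries again. Exact-20-bp
assembler gaps, whose flanks truly overlap by convention, are merged by
direct flank-overlap detection. Gaps that survive are resized from
insert-size evidence so their N-run lengths estimate genomic distance again.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .coords import CoordinateMap
from .mapping import RefIndex, map_reads
from .model import Assembly, ReadPairSet, Sequence, find_n_stretches, revcomp

_NONN_RUN = re.compile(r"[ACGT]+")


@dataclass
class GapTask:
    """One gap being worked: coordinates track the current assembly state."""

    seq_id: str
    orig_start: int  # input coordinates, stable across iterations
    orig_end: int
    start: int  # current coordinates of the N-run
    end: int
    status: str = "open"  # open | extended_left | extended_right | closed | merged | resized
    inserted: str = ""  # full content now occupying the original N-run interval
    added_left: int = 0
    added_right: int = 0
    iterations_used: int = 0
    note: str = ""
    consumed_right: int = 0  # right-flank bases removed by overlap splicing
    left_acc: str = ""  # accumulated flank extensions across iterations
    right_acc: str = ""


@dataclass
class GapReport:
    tasks: list[GapTask] = field(default_factory=list)
    skipped_sequences: list[str] = field(default_factory=list)
    coord_map: CoordinateMap = field(default_factory=CoordinateMap)

    def closed(self) -> list[GapTask]:
        return [t for t in self.tasks if t.status in ("closed", "merged")]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "seq_id\torig_start\torig_end\tstatus\tadded_left\tadded_right\t"
                "iterations\tnote\tinserted\n"
            )
            for t in self.tasks:
                fh.write(
                    f"{t.seq_id}\t{t.orig_start}\t{t.orig_end}\t{t.status}\t"
                    f"{t.added_left}\t{t.added_right}\t{t.iterations_used}\t{t.note}\t"
                    f"{t.inserted}\n"
                )


class _ConsensusWalker:
    """Greedy k-mer consensus extension over a pool of recruited reads."""

    def __init__(self, pool: list[str], k: int, min_support: int = 3,
                 min_agree: float = 0.75, branch_frac: float = 0.4):
        self.k = k
        self.min_support = min_support
        self.min_agree = min_agree
        self.branch_frac = branch_frac
        nxt: dict[str, Counter] = {}
        for seq in pool:
            for i in range(len(seq) - k):
                nxt.setdefault(seq[i : i + k], Counter())[seq[i + k]] += 1
        self.nxt = nxt

    def extend(self, anchor: str, max_ext: int) -> tuple[str, str]:
        """Extend rightward from the anchor; returns (extension, stop_reason)."""
        if len(anchor) < self.k:
            return "", "anchor-too-short"
        cur = anchor[-self.k :]
        ext = []
        while len(ext) < max_ext:
            counts = self.nxt.get(cur)
            if not counts:
                return "".join(ext), "no-overlap"
            total = sum(counts.values())
            (b1, c1), *rest = counts.most_common(2)
            if total < self.min_support:
                return "".join(ext), "low-support"
            if rest and rest[0][1] / total >= self.branch_frac and c1 / total >= self.branch_frac:
                return "".join(ext), "repeat-ambiguous"
            if c1 / total < self.min_agree:
                return "".join(ext), "no-consensus"
            ext.append(b1)
            cur = cur[1:] + b1
        return "".join(ext), "step-limit"


def _splice_overlap(left: str, right: str, k: int, max_mismatch: int = 1) -> int:
    """Largest overlap length o >= k with <= max_mismatch mismatches, else 0."""
    for o in range(min(len(left), len(right)), k - 1, -1):
        mm = 0
        ls = left[-o:]
        rs = right[:o]
        for a, b in zip(ls, rs):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return o
    return 0


def _has_anchor_segment(residues: str, min_anchor: int) -> bool:
    return any(m.end() - m.start() >= min_anchor for m in _NONN_RUN.finditer(residues))


def close_gaps(
    a: Assembly,
    reads: ReadPairSet,
    k: int = 31,
    iterations: int = 6,
    min_anchor: int = 300,
    flank_window: int = 400,
    min_support: int = 3,
    min_agree: float = 0.75,
    branch_frac: float = 0.4,
    max_mismatch_frac: float = 0.04,
) -> tuple[Assembly, GapReport]:
    """Close interior N-stretch gaps by iterative anchored read extension.

    Per iteration reads are remapped to the working assembly; for each open
    gap, pairs with one mate anchored within an insert length of a flank and
    oriented gap-ward are recruited, and the dangling mates drive a k-mer
    consensus walk from each flank (step limited to one read length, needing
    >= ``min_support`` reads and > ``min_agree`` agreement per base; a second
    branch at >= ``branch_frac`` stops the walk as repeat-ambiguous). When
    the two extensions overlap by >= k with at most one mismatch the gap is
    spliced closed; otherwise the recorded N-run shrinks by the bases gained.
    """
    out = a.copy()
    report = GapReport()
    scaffolds = {s.id: s for s in out.scaffolds}
    for s in out.scaffolds:
        if not _has_anchor_segment(s.residues, min_anchor):
            report.skipped_sequences.append(s.id)
    tasks: list[GapTask] = []
    for s in out.scaffolds:
        if s.id in report.skipped_sequences:
            continue
        for ns in find_n_stretches(s, min_len=2):
            tasks.append(GapTask(s.id, ns.start, ns.end, ns.start, ns.end))
    report.tasks = tasks
    imax = reads.insert_max
    rl = reads.read_len

    for it in range(1, iterations + 1):
        open_tasks = [t for t in tasks if t.status not in ("closed", "merged")]
        if not open_tasks:
            break
        mapres = map_reads(reads, out, max_mismatch_frac=max_mismatch_frac)
        by_seq: dict[str, list] = {}
        for m in mapres.placed:
            by_seq.setdefault(m.seq_id, []).append(m)

        # process gaps right-to-left per scaffold so edits keep coordinates valid
        for t in sorted(open_tasks, key=lambda t: (t.seq_id, -t.start)):
            scaffold = scaffolds[t.seq_id]
            res = scaffold.residues
            pool: list[str] = []
            for m in by_seq.get(t.seq_id, []):
                anchored_left = m.strand == "+" and t.start - imax <= m.start and m.ref_end <= t.start + 8
                anchored_right = m.strand == "-" and t.end - 8 <= m.start <= t.end + imax
                if not (anchored_left or anchored_right):
                    continue
                pair = reads.pairs[m.pair_index]
                mate_seq = pair.seq2 if m.mate == 1 else pair.seq1
                pool.append(revcomp(mate_seq) if m.strand == "+" else mate_seq)
            if not pool:
                t.iterations_used = it
                continue
            walker_f = _ConsensusWalker(pool, k, min_support, min_agree, branch_frac)
            walker_r = _ConsensusWalker([revcomp(p) for p in pool], k, min_support,
                                        min_agree, branch_frac)
            lf0 = max(0, t.start - flank_window)
            left_anchor = res[lf0 : t.start]
            right_anchor = res[t.end : t.end + flank_window]
            if "N" in left_anchor:
                left_anchor = left_anchor[left_anchor.rfind("N") + 1 :]
            if "N" in right_anchor:
                right_anchor = right_anchor[: right_anchor.find("N")]
            ext_l, reason_l = walker_f.extend(left_anchor, rl)
            ext_r_rc, reason_r = walker_r.extend(revcomp(right_anchor), rl)
            ext_r = revcomp(ext_r_rc)
            if "repeat-ambiguous" in (reason_l, reason_r):
                t.note = "repeat-ambiguous"
            t.iterations_used = it
            if not ext_l and not ext_r:
                continue
            left_str = left_anchor + ext_l
            right_str = ext_r + right_anchor
            o = _splice_overlap(left_str, right_str, k)
            gained_l = len(ext_l)
            gained_r = len(ext_r)
            old_len = t.end - t.start
            if o:
                # overlap of the extended flanks: splice the gap closed.
                # Content between the current flanks is ext_l plus whatever
                # of ext_r lies beyond the overlap; an overlap reaching past
                # ext_r consumes duplicated right-flank bases.
                consumed_right = max(0, o - gained_r)
                between = ext_l + (ext_r[o:] if o < gained_r else "")
                scaffold.residues = res[: t.start] + between + res[t.end + consumed_right :]
                delta = len(between) - old_len - consumed_right
                t.status = "closed"
                # consumption beyond this iteration's ext_r first eats earlier
                # accumulated right extensions, then true original flank
                consumed_from_acc = min(consumed_right, len(t.right_acc))
                t.inserted = t.left_acc + between + t.right_acc[consumed_from_acc:]
                t.added_left += gained_l
                t.added_right += gained_r
                t.consumed_right = consumed_right - consumed_from_acc
                t.end = t.start + len(between)
            else:
                new_n = max(2, old_len - gained_l - gained_r)
                scaffold.residues = (
                    res[: t.start] + ext_l + "N" * new_n + ext_r + res[t.end :]
                )
                delta = (gained_l + new_n + gained_r) - old_len
                t.added_left += gained_l
                t.added_right += gained_r
                t.left_acc += ext_l
                t.right_acc = ext_r + t.right_acc
                if gained_l:
                    t.status = "extended_left"
                elif gained_r:
                    t.status = "extended_right"
                t.start = t.start + gained_l
                t.end = t.start + new_n
            if delta:
                for u in tasks:
                    if u.seq_id == t.seq_id and u is not t and u.start > t.end:
                        u.start += delta
                        u.end += delta

    for t in tasks:
        if t.status == "closed":
            new_len = len(t.inserted)
        else:
            t.inserted = t.left_acc + "N" * (t.end - t.start) + t.right_acc
            new_len = len(t.inserted)
        report.coord_map.add(
            t.seq_id, t.orig_start, t.orig_end + t.consumed_right, new_len
        )
    return out, report


def merge_convention_gaps(
    a: Assembly,
    overlap_min: int = 20,
    max_mismatch_frac: float = 0.02,
    gap_len: int = 20,
    max_trim: int = 10,
    search: int = 200,
) -> tuple[Assembly, GapReport]:
    """Merge exact-20-bp assembler gaps whose flanks truly overlap.

    After trimming up to ``max_trim`` bases of potentially low-quality end
    sequence from either flank, the largest flank overlap of at least
    ``overlap_min`` bases with a mismatch fraction <= ``max_mismatch_frac``
    is spliced, removing the Ns and the duplicated bases. Gaps with no such
    overlap are left untouched.
    """
    out = a.copy()
    report = GapReport()
    for scaffold in out.scaffolds:
        runs = [r for r in find_n_stretches(scaffold) if r.length == gap_len]
        for ns in sorted(runs, key=lambda r: -r.start):
            res = scaffold.residues
            left = res[max(0, ns.start - search) : ns.start]
            right = res[ns.end : ns.end + search]
            hit = None
            for o in range(min(len(left), len(right), search), overlap_min - 1, -1):
                allowed = int(max_mismatch_frac * o)
                for t_l in range(0, max_trim + 1):
                    if o + t_l > len(left):
                        continue
                    ls = left[len(left) - t_l - o : len(left) - t_l] if t_l else left[-o:]
                    for t_r in range(0, max_trim + 1):
                        if o + t_r > len(right):
                            continue
                        rs = right[t_r : t_r + o]
                        mm = sum(1 for x, y in zip(ls, rs) if x != y)
                        if mm <= allowed:
                            hit = (o, t_l, t_r)
                            break
                    if hit:
                        break
                if hit:
                    break
            task = GapTask(scaffold.id, ns.start, ns.end, ns.start, ns.end)
            report.tasks.append(task)
            if hit is None:
                task.note = "no-overlap"
                continue
            o, t_l, t_r = hit
            # keep the left copy of the overlap, resume after the right copy
            new_res = res[: ns.start - t_l] + res[ns.end + t_r + o :]
            removed = (ns.end + t_r + o) - (ns.start - t_l)
            scaffold.residues = new_res
            task.status = "merged"
            task.note = f"overlap={o};trim_l={t_l};trim_r={t_r}"
            report.coord_map.add(scaffold.id, ns.start - t_l, ns.end + t_r + o, 0)
    return out, report


def resize_n_stretches(
    a: Assembly,
    reads: ReadPairSet,
    min_spanning: int = 5,
) -> tuple[Assembly, GapReport]:
    """Re-estimate surviving N-run lengths from insert-size evidence.

    For pairs whose mates anchor on opposite flanks of a gap, the gap length
    estimate is the mean insert size minus the bases the pair covers outside
    the gap; the new N-length is the rounded median over spanning pairs,
    clamped to [2, insert_max]. Gaps with fewer than ``min_spanning``
    spanning pairs keep their recorded length; estimates of zero or less are
    clamped to 2 and flagged as merge candidates.
    """
    out = a.copy()
    report = GapReport()
    mapres = map_reads(reads, out)
    pairs_by_seq: dict[str, list[tuple[int, int, int, int]]] = {}
    by_pair: dict[int, list] = {}
    for m in mapres.placed:
        by_pair.setdefault(m.pair_index, []).append(m)
    for pi, ms in by_pair.items():
        if len(ms) != 2:
            continue
        m1, m2 = ms
        if m1.seq_id != m2.seq_id or m1.strand == m2.strand:
            continue
        fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
        pairs_by_seq.setdefault(fwd.seq_id, []).append(
            (fwd.start, fwd.ref_end, rev.start, rev.ref_end)
        )
    for scaffold in out.scaffolds:
        spans = pairs_by_seq.get(scaffold.id, [])
        arr = np.array(spans, dtype=np.int64).reshape(-1, 4)
        for ns in sorted(find_n_stretches(scaffold, min_len=2), key=lambda r: -r.start):
            task = GapTask(scaffold.id, ns.start, ns.end, ns.start, ns.end)
            report.tasks.append(task)
            if len(arr) == 0:
                task.note = "no-spanning-pairs"
                continue
            sel = (arr[:, 1] <= ns.start) & (arr[:, 2] >= ns.end)
            sub = arr[sel]
            if len(sub) < min_spanning:
                task.note = f"spanning-pairs={len(sub)}"
                continue
            outside = (ns.start - sub[:, 0]) + (sub[:, 3] - ns.end)
            est = int(round(float(np.median(reads.insert_mean - outside))))
            new_len = min(max(est, 2), reads.insert_max)
            if est <= 0:
                task.note = "merge-candidate"
            res = scaffold.residues
            scaffold.residues = res[: ns.start] + "N" * new_len + res[ns.end :]
            task.status = "resized"
            task.end = ns.start + new_len
            report.coord_map.add(scaffold.id, ns.start, ns.end, new_len)
    return out, report


def trim_terminal_ns(a: Assembly) -> tuple[Assembly, list[str]]:
    """Strip leading and trailing N-runs; drop (and list) all-N sequences."""
    scaffolds, contigs, dropped = [], [], []
    for group, target in ((a.scaffolds, scaffolds), (a.contigs, contigs)):
        for s in group:
            trimmed = s.residues.strip("N")
            if not trimmed:
                dropped.append(s.id)
                continue
            target.append(Sequence(s.id, trimmed))
    return Assembly(scaffolds=scaffolds, contigs=contigs, provenance=a.provenance), dropped
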