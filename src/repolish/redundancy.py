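"""Removal of redundant contigs: near-identical containments of larger sequences.

A contig is redundant when at least 99% of it aligns at 98%+ identity to a
strictly larger contig or to any scaffold. Candidates are found by seeding
with short k-mers (low-complexity seeds masked, in the spirit of dust
filtering) and verified by gapped alignment; N positions never count as
matches. The removal set is computed against the unmodified assembly and
applied afterwards, so the operation is order-independent and idempotent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import edlib

from .model import Assembly, Sequence
from .mapping import parse_cigar

logger = logging.getLogger(__name__)


@dataclass
class ContainmentResult:
    query_id: str
    subject_id: str
    query_coverage: float
    identity: float


def _low_complexity(seed: str) -> bool:
    """Dust-style mask: a seed dominated by one base or a dinucleotide repeat."""
    counts = Counter(seed)
    if max(counts.values()) / len(seed) >= 0.8:
        return True
    if len(set(seed[i : i + 2] for i in range(len(seed) - 1))) <= 2:
        return True
    return False


def _seeds(seq: str, k: int, stride: int) -> list[tuple[int, str]]:
    out = []
    for pos in range(0, max(1, len(seq) - k + 1), stride):
        s = seq[pos : pos + k]
        if len(s) == k and "N" not in s and not _low_complexity(s):
            out.append((pos, s))
    return out


def align_containment(query: Sequence, subject: Sequence, k: int = 15) -> ContainmentResult:
    """Coverage and identity of the query within the subject.

    Coverage is the fraction of (non-N) query bases placed in aligned columns;
    identity is exact matches over all aligned columns of the covered portion.
    A query too short for seeding, or without any seed hit, gets coverage 0.
    """
    zero = ContainmentResult(query.id, subject.id, 0.0, 0.0)
    q, t = query.residues, subject.residues
    if len(q) < k:
        logger.warning("query %s shorter than seed size %d", query.id, k)
        return zero
    stride = max(1, len(q) // 64)
    seeds = _seeds(q, k, stride)
    if not seeds or not any(s in t for _, s in seeds[:: max(1, len(seeds) // 8)]):
        return zero
    max_ed = max(8, int(0.25 * len(q)))
    res = edlib.align(q, t, mode="HW", task="path", k=max_ed)
    if res["editDistance"] < 0:
        return zero
    cigar = parse_cigar(res["cigar"])
    t0 = res["locations"][0][0]
    matches = 0
    columns = 0
    covered_q = 0
    qp, tp = 0, t0
    for op, n in cigar:
        columns += n
        if op == "=":
            nn = sum(1 for i in range(n) if q[qp + i] != "N")
            matches += nn
            covered_q += nn
            qp += n
            tp += n
        elif op == "X":
            covered_q += sum(1 for i in range(n) if q[qp + i] != "N")
            qp += n
            tp += n
        elif op == "I":
            qp += n
        else:
            tp += n
    q_len_non_n = sum(1 for c in q if c != "N")
    if q_len_non_n == 0:
        return zero
    return ContainmentResult(
        query.id,
        subject.id,
        covered_q / len(q),
        matches / columns if columns else 0.0,
    )


def remove_redundant_contigs(
    a: Assembly,
    min_cov: float = 0.99,
    min_ident: float = 0.98,
    k: int = 15,
) -> tuple[Assembly, list[ContainmentResult]]:
    """Drop contigs contained in a strictly larger contig or any scaffold.

    Scaffolds are never removed. Two identical contigs of equal length are
    both kept (neither is a strictly larger container); such ties are logged.
    Returns the filtered assembly and the removal report.
    """
    containers: list[Sequence] = list(a.scaffolds) + list(a.contigs)
    # seed index: kmer -> container indices
    index: dict[str, list[int]] = {}
    kk = max(k, 15)
    for ci, cont in enumerate(containers):
        res = cont.residues
        for pos in range(0, max(1, len(res) - kk + 1), 4):
            s = res[pos : pos + kk]
            if "N" not in s and not _low_complexity(s):
                index.setdefault(s, []).append(ci)

    n_scaffolds = len(a.scaffolds)
    removed: list[ContainmentResult] = []
    removed_ids: set[str] = set()
    for qi, contig in enumerate(a.contigs):
        votes: Counter = Counter()
        # odd query stride, coprime with the index stride of 4, so seed
        # positions sweep every residue class of the container index
        stride = max(1, len(contig) // 32) | 1
        for _, s in _seeds(contig.residues, kk, stride):
            for ci in index.get(s, ()):
                votes[ci] += 1
        hit = None
        for ci, _ in votes.most_common(6):
            cont = containers[ci]
            is_self = ci - n_scaffolds == qi
            if is_self:
                continue
            strictly_larger = ci < n_scaffolds or len(cont) > len(contig)
            r = align_containment(contig, cont, k=k)
            if r.query_coverage >= min_cov and r.identity >= min_ident:
                if not strictly_larger:
                    logger.info(
                        "tie: contig %s matches equal-or-smaller contig %s; both kept",
                        contig.id, cont.id,
                    )
                    continue
                hit = r
                break
        if hit is not None:
            removed.append(hit)
            removed_ids.add(contig.id)
    out = Assembly(
        scaffolds=[Sequence(s.id, s.residues) for s in a.scaffolds],
        contigs=[Sequence(c.id, c.residues) for c in a.contigs if c.id not in removed_ids],
        provenance=a.provenance,
    )
    return out, removed


def write_removal_report(removed: list[ContainmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tcontainer_id\tcoverage\tidentity\n")
        for r in removed:
            fh.write(f"{r.query_id}\t{r.subject_id}\t{r.query_coverage:.4f}\t{r.identity:.4f}\n")
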