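"""NBS-LRR domain architecture, NBS-domain phylogeny, and orthology pairing.

Domain architectures are classified from the ordered domain content around
the NBS domain (TIR or CC prefix, LRR suffix). The phylogeny is a
neighbor-joining tree over pairwise p-distances of globally aligned NBS
domain sequences — a desk-scale, deterministic substitute for alignment-
pipeline trees, adequate because the claim being quantified (clade vs.
genomic sub-cluster concordance) is robust to tree method. Orthologs across
species are paired by reciprocal best full-protein identity; ties are left
unpaired and flagged as cluster-level orthology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .model import DomainedProtein

logger = logging.getLogger(__name__)

ARCHITECTURE_CLASSES = ("TN", "TNL", "N", "NL", "CN", "CNL")


def classify_architecture(p: DomainedProtein) -> str:
    """Domain-architecture class from TIR/CC prefix and LRR suffix around NBS.

    Raises ValueError when no NBS domain is present (candidate pseudogene
    path; such sequences are not classifiable R-genes).
    """
    kinds = p.domain_kinds()
    if "NBS" not in kinds:
        raise ValueError(f"{p.protein_id}: no NBS domain; not a classifiable R-gene")
    nbs_i = kinds.index("NBS")
    prefix = ""
    if "TIR" in kinds[:nbs_i]:
        prefix = "T"
    elif "CC" in kinds[:nbs_i]:
        prefix = "C"
    suffix = "L" if any(k.startswith("LRR") for k in kinds[nbs_i + 1 :]) else ""
    return f"{prefix}N{suffix}"


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _aligned_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Identity over aligned columns, terminal gaps excluded."""
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    i0 = 0
    i1 = len(sa)
    while i0 < i1 and (sa[i0] == "-" or sb[i0] == "-"):
        i0 += 1
    while i1 > i0 and (sa[i1 - 1] == "-" or sb[i1 - 1] == "-"):
        i1 -= 1
    cols = i1 - i0
    if cols <= 0:
        return 0.0
    matches = sum(1 for x, y in zip(sa[i0:i1], sb[i0:i1]) if x == y and x != "-")
    return matches / cols


def nbs_distance_matrix(proteins: list[DomainedProtein]) -> DistanceMatrix:
    """Pairwise p-distances (1 - identity) over globally aligned NBS domains."""
    with_nbs = [p for p in proteins if p.domain_seq("NBS")]
    if len(with_nbs) < 3:
        raise ValueError("need at least 3 proteins with an NBS domain")
    ids = sorted(p.protein_id for p in with_nbs)
    by_id = {p.protein_id: p for p in with_nbs}
    aligner = _protein_aligner()
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ident = _aligned_identity(
            by_id[ids[i]].domain_seq("NBS"), by_id[ids[j]].domain_seq("NBS"), aligner
        )
        d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(d, ids)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Standard neighbor-joining tree from a distance matrix.

    Labels are canonicalized to sorted order first so exchangeable inputs
    produce identical newick output (deterministic tie-breaking).
    """
    ids = sorted(d.ids)
    d = d.filter(ids)
    tree = nj(d)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def _bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets under each internal edge of the (unrooted) tree."""
    all_leaves = frozenset(l.name for l in tree.tips())
    parts = []
    for node in tree.non_tips(include_self=False):
        parts.append(frozenset(l.name for l in node.tips()))
    parts.append(all_leaves)
    return parts


@dataclass
class ConcordanceReport:
    fraction_monophyletic: float
    per_cluster: dict[str, bool] = field(default_factory=dict)


def cluster_concordance(tree: TreeNode, cluster_map: dict[str, str]) -> ConcordanceReport:
    """Fraction of genomic sub-clusters (size >= 2) monophyletic on the tree.

    Monophyly on an unrooted tree means an edge separates the cluster's
    leaves from all other leaves; clusters containing every leaf, or of size
    one, are trivially concordant and excluded from the fraction unless no
    larger cluster exists.
    """
    leaves = {l.name for l in tree.tips()}
    missing = leaves - set(cluster_map)
    if missing:
        raise ValueError(f"leaves without cluster label: {sorted(missing)}")
    clusters: dict[str, set[str]] = {}
    for leaf, label in cluster_map.items():
        if leaf in leaves:
            clusters.setdefault(label, set()).add(leaf)
    parts = set(_bipartitions(tree))
    per: dict[str, bool] = {}
    for label, members in clusters.items():
        if len(members) < 2:
            continue
        m = frozenset(members)
        comp = frozenset(leaves - members)
        per[label] = (m in parts) or (comp in parts) or not comp
    frac = sum(per.values()) / len(per) if per else 1.0
    return ConcordanceReport(frac, per)


def reciprocal_best_hits(
    set_a: list[DomainedProtein], set_b: list[DomainedProtein]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair proteins across species by reciprocal best full-protein identity.

    Returns (pairs, ambiguous): a pair (a, b) requires b to be a's unique
    best-identity match in B and vice versa; a protein whose best identity is
    tied between two candidates stays unpaired and is flagged (cluster-level
    orthology, the unresolvable case among near-identical paralogs).
    """
    if not set_a or not set_b:
        return [], []
    aligner = _protein_aligner()
    ident: dict[tuple[str, str], float] = {}
    for pa in set_a:
        for pb in set_b:
            ident[(pa.protein_id, pb.protein_id)] = _aligned_identity(
                pa.sequence, pb.sequence, aligner
            )

    def best(pid: str, others: list[DomainedProtein], forward: bool) -> str | None:
        scores = [
            (ident[(pid, o.protein_id)] if forward else ident[(o.protein_id, pid)],
             o.protein_id)
            for o in others
        ]
        scores.sort(reverse=True)
        if len(scores) > 1 and np.isclose(scores[0][0], scores[1][0], atol=1e-9):
            return None
        return scores[0][1]

    pairs = []
    ambiguous = []
    for pa in set_a:
        ba = best(pa.protein_id, set_b, True)
        if ba is None:
            ambiguous.append(pa.protein_id)
            logger.info("%s: tied best hits; cluster-level orthology", pa.protein_id)
            continue
        bb = best(ba, set_a, False)
        if bb is None:
            ambiguous.append(pa.protein_id)
            continue
        if bb == pa.protein_id:
            pairs.append((pa.protein_id, ba))
    return pairs, ambiguous


def read_domain_table(path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a domain TSV (protein_id, kind, start, end; 0-based half-open)."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, kind, s, e = line.rstrip("\n").split("\t")
            out.setdefault(pid, []).append((kind, int(s), int(e)))
    return out
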