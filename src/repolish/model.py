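"""Core domain types shared across the refinement and analysis stages.

Coordinates are 0-based half-open everywhere inside the package; the GFF3 and
VCF readers/writers in :mod:`repolish.io` convert to and from the 1-based
conventions of those formats at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Sequence:
    """A named DNA or protein sequence, residues upper-cased on construction."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NStretch:
    """A maximal run of uncertain nucleotides (N) within one sequence."""

    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


_N_RUN = re.compile(r"N+")


def find_n_stretches(seq: Sequence, min_len: int = 1) -> list[NStretch]:
    """Maximal N-runs of length >= ``min_len``, sorted by start position."""
    return [
        NStretch(seq.id, m.start(), m.end())
        for m in _N_RUN.finditer(seq.residues)
        if m.end() - m.start() >= min_len
    ]


def has_n_stretch(residues: str, min_len: int = 2) -> bool:
    return "N" * min_len in residues


@dataclass
class Assembly:
    """Scaffolds (sequences that may carry N-stretches) plus free contigs.

    A contig, per the classification used throughout, is a sequence without
    any N-run longer than one base; the draft assemblies this package targets
    keep single-N noise in contigs but confine true gaps to scaffolds.
    """

    scaffolds: list[Sequence] = field(default_factory=list)
    contigs: list[Sequence] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scaffolds] + [c.id for c in self.contigs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sequence ids in assembly: {sorted(dupes)}")

    def sequences(self) -> list[Sequence]:
        return list(self.scaffolds) + list(self.contigs)

    def get(self, seq_id: str) -> Sequence:
        for s in self.sequences():
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def copy(self) -> "Assembly":
        return Assembly(
            scaffolds=[Sequence(s.id, s.residues) for s in self.scaffolds],
            contigs=[Sequence(c.id, c.residues) for c in self.contigs],
            provenance=self.provenance,
        )


@dataclass
class MetricsReport:
    """Assembly bookkeeping metrics (counts, lengths and N content)."""

    n_scaffolds: int
    n_contigs: int
    total_len: int
    total_len_no_n: int
    n_count: int
    n_stretches_gt1: int
    n_stretches_exact20: int
    scaffold_len: int
    scaffold_len_no_n: int
    contig_len: int
    contig_len_no_n: int
    mean_nstretch_len: float

    def as_rows(self) -> list[tuple[str, object]]:
        return [
            ("Scaffolds", self.n_scaffolds),
            ("Contigs", self.n_contigs),
            ("Length (bp)", self.total_len),
            ("Length, no Ns (bp)", self.total_len_no_n),
            ("Stretches of Ns (#N > 1)", self.n_stretches_gt1),
            ("Stretches of Ns (#N = 20)", self.n_stretches_exact20),
            ("Number of Ns", self.n_count),
            ("Length of scaffolds (bp)", self.scaffold_len),
            ("Length of scaffolds, no Ns (bp)", self.scaffold_len_no_n),
            ("Length of contigs (bp)", self.contig_len),
            ("Length of contigs, no Ns (bp)", self.contig_len_no_n),
            ("Average N-stretch size (bp)", round(self.mean_nstretch_len, 1)),
        ]


def assembly_metrics(a: Assembly) -> MetricsReport:
    """Compute the standard improvement metrics for an assembly.

    ``n_stretches_gt1`` counts maximal N-runs of length >= 2;
    ``n_stretches_exact20`` counts runs of exactly 20 (the assembler's
    adjacent-contig-overlap convention); ``mean_nstretch_len`` is total Ns
    divided by the number of runs of length >= 2.
    """
    scaffold_len = sum(len(s) for s in a.scaffolds)
    contig_len = sum(len(c) for c in a.contigs)
    n_count = sum(s.residues.count("N") for s in a.sequences())
    runs = [r for s in a.sequences() for r in find_n_stretches(s)]
    gt1 = sum(1 for r in runs if r.length >= 2)
    exact20 = sum(1 for r in runs if r.length == 20)
    scaffold_n = sum(s.residues.count("N") for s in a.scaffolds)
    return MetricsReport(
        n_scaffolds=len(a.scaffolds),
        n_contigs=len(a.contigs),
        total_len=scaffold_len + contig_len,
        total_len_no_n=scaffold_len + contig_len - n_count,
        n_count=n_count,
        n_stretches_gt1=gt1,
        n_stretches_exact20=exact20,
        scaffold_len=scaffold_len,
        scaffold_len_no_n=scaffold_len - scaffold_n,
        contig_len=contig_len,
        contig_len_no_n=contig_len - (n_count - scaffold_n),
        mean_nstretch_len=(n_count / gt1) if gt1 else 0.0,
    )


@dataclass
class GeneModel:
    """A gene with exon and CDS intervals on a genomic sequence.

    Intervals are 0-based half-open, sorted, non-overlapping and given in
    genomic order regardless of strand. ``class_label`` carries the
    NBS-LRR domain-architecture class when known (TN, TNL, N, NL, CN, CNL).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    class_label: str | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for ivs in (self.exons, self.cds):
            ivs.sort()
            for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping intervals in {self.gene_id}")
        cds_len = sum(e - s for s, e in self.cds)
        if self.cds and cds_len % 3 != 0 and not self.partial:
            raise ValueError(
                f"CDS length {cds_len} of {self.gene_id} not divisible by 3 "
                "(flag partial=True for fragments)"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_sequence(self, genome: str) -> str:
        """Spliced CDS in translation order (reverse-complemented on '-')."""
        s = "".join(genome[a:b] for a, b in self.cds)
        return revcomp(s) if self.strand == "-" else s

    def introns(self) -> list[tuple[int, int]]:
        return [(a1, b0) for (_, a1), (b0, _) in zip(self.exons, self.exons[1:])]


@dataclass(frozen=True)
class Variant:
    """A called SNP or short indel, in 0-based coordinates.

    For indels ``ref``/``alt`` are the unanchored event alleles (the VCF
    writer adds the anchor base on emission): an insertion has ``ref == ''``
    and ``alt`` the inserted bases; a deletion has ``alt == ''``.
    """

    seq_id: str
    pos: int
    ref: str
    alt: str
    type: str  # snp | ins | del
    zygosity: str  # homo | hetero
    depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.type not in ("snp", "ins", "del"):
            raise ValueError(f"bad variant type {self.type!r}")


@dataclass
class EffectRecord:
    """A variant's classified consequence on one gene model."""

    variant: Variant
    gene_id: str
    region: str  # exon | intron | splice_site | intergenic
    consequence: str  # missense | nonsense | silent | frameshift | inframe | n/a
    aa_change: str = ""


@dataclass
class DomainedProtein:
    """Protein sequence plus ordered domain intervals and genomic locus."""

    protein_id: str
    sequence: str
    domains: list[tuple[str, int, int]]  # (kind, start, end), 0-based half-open
    seq_id: str = ""
    genomic_start: int = 0
    strand: str = "+"
    cluster_label: str = ""

    def __post_init__(self) -> None:
        self.domains.sort(key=lambda d: d[1])
        for kind, s, e in self.domains:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(
                    f"domain {kind} [{s},{e}) outside protein {self.protein_id}"
                )

    def domain_kinds(self) -> list[str]:
        return [k for k, _, _ in self.domains]

    def domain_seq(self, kind: str) -> str | None:
        """Sequence of the first domain of the given kind, or None."""
        for k, s, e in self.domains:
            if k == kind:
                return self.sequence[s:e]
        return None


@dataclass
class ReadPair:
    """One innie-oriented mate pair (sequences as sequenced, 5'->3')."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class ReadPairSet:
    """Mated reads plus the insert-size statistics of the library."""

    pairs: list[ReadPair]
    read_len: int
    insert_mean: float
    insert_min: int
    insert_max: int

    def __len__(self) -> int:
        return len(self.pairs)
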