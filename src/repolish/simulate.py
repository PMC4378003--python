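"""Synthetic truth/draft/read triples for end-to-end refinement testing.

The generator emulates the situation the pipeline targets: a region of a
plant genome carrying a tandemly duplicated cluster of NBS-LRR-like genes,
assembled into a draft that suffers from unsequenced gaps (N-stretches whose
recorded lengths only estimate true distances, plus exact-20-bp assembler
gaps whose flanks truly overlap), isolated substitution errors, homopolymer
length errors, and redundant contigs — together with an Illumina-like
paired-end read set (2 x 152 bp, insert 152-645 bp with mean 509).

Every injected lesion is recorded in an :class:`ErrorLedger`; replaying the
ledger over the truth reproduces the draft byte-exactly, which is what makes
ground-truth recovery scoring possible downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from .model import (
    Assembly,
    DomainedProtein,
    GeneModel,
    ReadPair,
    ReadPairSet,
    Sequence,
    revcomp,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for one simulated region.

    Defaults are the conditions used throughout validation: a 100-kb region,
    eight cluster genes in four proximity sub-clusters diverged at 5%
    substitutions/site, 20 gaps (a quarter of them exact-20-bp assembler
    gaps), one substitution error per kb, 0.3 homopolymer indel events per
    kb, five redundant contigs, and 30x 2x152 bp pairs with a 509-bp mean
    insert truncated to [152, 645].
    """

    region_len: int = 100_000
    n_cluster_genes: int = 8
    n_subclusters: int = 4
    duplication_divergence: float = 0.05
    gap_count: int = 20
    gap_len_min: int = 50
    gap_len_max: int = 500
    exact20_fraction: float = 0.25
    substitution_error_rate: float = 1.0  # errors per kb
    homopolymer_indel_rate: float = 0.3  # events per kb, runs >= 4 only
    redundant_contig_count: int = 5
    redundant_divergence_max: float = 0.01
    read_len: int = 152
    insert_mean: float = 509.0
    insert_sd: float = 80.0
    insert_min: int = 152
    insert_max: int = 645
    coverage: float = 30.0
    base_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.insert_min <= self.insert_mean <= self.insert_max):
            raise ValueError("insert_min <= insert_mean <= insert_max required")
        if self.read_len > self.insert_min:
            raise ValueError("read_len must not exceed insert_min")
        for name in ("substitution_error_rate", "homopolymer_indel_rate",
                     "base_error_rate", "duplication_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Lesion:
    """One injected defect, recorded in truth and draft coordinates."""

    kind: str  # gap | gap20 | substitution | hp_insertion | hp_deletion | redundant_contig
    truth_start: int
    truth_end: int
    draft_start: int = -1
    draft_end: int = -1
    payload: str = ""


@dataclass
class ErrorLedger:
    """Ground-truth record of every lesion; replay(truth) == draft."""

    records: list[Lesion] = field(default_factory=list)
    scaffold_id: str = "scaffold_1"

    def of_kind(self, *kinds: str) -> list[Lesion]:
        return [r for r in self.records if r.kind in kinds]

    def replay(self, truth: Sequence) -> Assembly:
        """Rebuild the draft assembly deterministically from the ledger."""
        inplace = sorted(
            (r for r in self.records if r.kind != "redundant_contig"),
            key=lambda r: r.truth_start,
        )
        parts: list[str] = []
        cursor = 0
        draft_pos = 0
        for r in inplace:
            parts.append(truth.residues[cursor : r.truth_start])
            draft_pos += r.truth_start - cursor
            if r.kind == "gap":
                n_len = int(r.payload)
                piece = "N" * n_len
            elif r.kind == "gap20":
                overlap = int(r.payload)
                piece = (
                    truth.residues[r.truth_start : r.truth_start + overlap] + "N" * 20
                )
            elif r.kind == "substitution":
                piece = r.payload.split(">")[1]
            else:  # hp_insertion / hp_deletion: payload "base:new_len"
                base, new_len = r.payload.split(":")
                piece = base * int(new_len)
            r.draft_start = draft_pos
            r.draft_end = draft_pos + len(piece)
            draft_pos += len(piece)
            parts.append(piece)
            cursor = r.truth_end
        parts.append(truth.residues[cursor:])
        scaffold = Sequence(self.scaffold_id, "".join(parts))
        contigs = []
        for i, r in enumerate(self.of_kind("redundant_contig"), 1):
            contigs.append(Sequence(f"redundant_{i}", r.payload))
        return Assembly(scaffolds=[scaffold], contigs=contigs, provenance="ledger replay")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\ttruth_start\ttruth_end\tdraft_start\tdraft_end\tpayload\n")
            for r in self.records:
                fh.write(
                    f"{r.kind}\t{r.truth_start}\t{r.truth_end}\t{r.draft_start}\t"
                    f"{r.draft_end}\t{r.payload}\n"
                )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal codons (no stops) + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float, keep_frame: bool = False) -> str:
    """Substitute bases at the given per-site rate.

    With ``keep_frame`` the sequence is treated as in-frame CDS and
    mutations that would create a stop codon are skipped.
    """
    s = list(seq)
    hits = np.flatnonzero(rng.random(len(s)) < rate)
    for i in hits:
        old = s[i]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        if keep_frame:
            cs = (i // 3) * 3
            codon = s[cs : cs + 3]
            codon[i - cs] = new
            if "".join(codon) in _STOPS or cs == 0:
                continue
        s[i] = new
    return "".join(s)


def generate_truth_region(
    cfg: SimConfig,
) -> tuple[Sequence, list[GeneModel], dict[str, str]]:
    """Generate a truth sequence carrying a duplicated gene cluster.

    Genes are arranged in ``cfg.n_subclusters`` proximal sub-clusters of
    tandem paralogs. Paralogs within a sub-cluster each diverge from the
    sub-cluster ancestor at ``duplication_divergence`` substitutions/site;
    sub-cluster ancestors diverge from a common root at four times that
    rate, so sub-clusters form clades of the duplication history.

    Returns the truth sequence, gene models, and a map gene_id -> sub-cluster
    label (A, B, C, ...).
    """
    rng = np.random.default_rng(cfg.seed)
    n_sub = min(cfg.n_subclusters, cfg.n_cluster_genes)
    # simplified NBS-LRR mimic: 3 exons, ~400 codons total
    exon_cds_lens = (240, 600, 360)  # per-exon CDS bp, total 1200 (400 aa)
    intron_len = 150
    gene_len = sum(exon_cds_lens) + 2 * intron_len
    spacer = 400
    sub_gap = 2000
    per_sub = [cfg.n_cluster_genes // n_sub] * n_sub
    for i in range(cfg.n_cluster_genes % n_sub):
        per_sub[i] += 1
    cluster_span = (
        sum(n * (gene_len + spacer) for n in per_sub) + (n_sub - 1) * sub_gap + 2000
    )
    if cfg.region_len < cluster_span + 4000:
        raise ValueError(
            f"region_len {cfg.region_len} too short for {cfg.n_cluster_genes} genes "
            f"(needs >= {cluster_span + 4000})"
        )

    root_cds = _random_cds(rng, sum(exon_cds_lens) // 3)
    root_introns = [
        "GT" + _random_dna(rng, intron_len - 4) + "AG" for _ in range(2)
    ]

    models: list[GeneModel] = []
    cluster_map: dict[str, str] = {}
    gene_seqs: list[tuple[int, str]] = []  # (gap before gene, gene sequence)
    pos_plan: list[tuple[str, str]] = []  # (gene_id, label)
    gene_idx = 0
    for si in range(n_sub):
        label = chr(ord("A") + si)
        anc_cds = _mutate(rng, root_cds, 4 * cfg.duplication_divergence, keep_frame=True)
        anc_introns = [_mutate(rng, intr, 4 * cfg.duplication_divergence) for intr in root_introns]
        for ci in range(per_sub[si]):
            gene_idx += 1
            gid = f"gene_{gene_idx:03d}"
            cds = _mutate(rng, anc_cds, cfg.duplication_divergence, keep_frame=True)
            introns = [_mutate(rng, intr, cfg.duplication_divergence) for intr in anc_introns]
            # preserve splice dinucleotides
            introns = ["GT" + intr[2:-2] + "AG" for intr in introns]
            e1, e2, e3 = (
                cds[: exon_cds_lens[0]],
                cds[exon_cds_lens[0] : exon_cds_lens[0] + exon_cds_lens[1]],
                cds[exon_cds_lens[0] + exon_cds_lens[1] :],
            )
            gseq = e1 + introns[0] + e2 + introns[1] + e3
            gap_before = sub_gap if (ci == 0 and si > 0) else spacer
            gene_seqs.append((gap_before, gseq))
            pos_plan.append((gid, label))

    leading = (cfg.region_len - cluster_span) // 2
    parts = []
    cursor = 0
    coords = []
    for (gap_before, gseq), (gid, label) in zip(gene_seqs, pos_plan):
        pad = leading if not parts else gap_before
        parts.append(_random_dna(rng, pad))
        cursor += pad
        coords.append((gid, label, cursor, cursor + len(gseq)))
        parts.append(gseq)
        cursor += len(gseq)
    parts.append(_random_dna(rng, cfg.region_len - cursor))
    truth = Sequence("truth_1", "".join(parts))

    for gid, label, g0, g1 in coords:
        b = [g0]
        b.append(b[-1] + exon_cds_lens[0])
        b.append(b[-1] + intron_len)
        b.append(b[-1] + exon_cds_lens[1])
        b.append(b[-1] + intron_len)
        b.append(b[-1] + exon_cds_lens[2])
        exons = [(b[0], b[1]), (b[2], b[3]), (b[4], b[5])]
        models.append(
            GeneModel(
                gene_id=gid,
                seq_id=truth.id,
                strand="+",
                exons=exons,
                cds=list(exons),
                class_label="TNL",
            )
        )
        cluster_map[gid] = label
    return truth, models, cluster_map


_DOMAIN_LAYOUT = {
    # fractions of the protein assigned to each domain per architecture class
    "TNL": (("TIR", 0.0, 0.25), ("NBS", 0.3, 0.65), ("LRR", 0.7, 1.0)),
    "TN": (("TIR", 0.0, 0.25), ("NBS", 0.3, 0.65)),
    "CNL": (("CC", 0.0, 0.2), ("NBS", 0.3, 0.65), ("LRR", 0.7, 1.0)),
    "CN": (("CC", 0.0, 0.2), ("NBS", 0.3, 0.65)),
    "NL": (("NBS", 0.1, 0.5), ("LRR", 0.6, 1.0)),
    "N": (("NBS", 0.1, 0.6),),
}


def proteins_from_models(
    truth: Sequence,
    models: list[GeneModel],
    cluster_map: dict[str, str] | None = None,
) -> list[DomainedProtein]:
    """Translate gene models and assign schematic domain intervals.

    Domain coordinates are placed by the architecture class (fractional
    layout over the protein) — a stand-in for externally supplied domain
    tables, adequate because downstream stages consume structure only.
    """
    from Bio.Seq import Seq

    out = []
    for m in models:
        aa = str(Seq(m.cds_sequence(truth.residues)).translate()).rstrip("*")
        layout = _DOMAIN_LAYOUT.get(m.class_label or "TNL", _DOMAIN_LAYOUT["TNL"])
        domains = [
            (kind, int(f0 * len(aa)), int(f1 * len(aa))) for kind, f0, f1 in layout
        ]
        out.append(
            DomainedProtein(
                protein_id=m.gene_id,
                sequence=aa,
                domains=domains,
                seq_id=m.seq_id,
                genomic_start=m.start,
                strand=m.strand,
                cluster_label=(cluster_map or {}).get(m.gene_id, ""),
            )
        )
    return out


_HP_RUN = re.compile(r"(A{4,}|C{4,}|G{4,}|T{4,})")


def degrade_assembly(
    truth: Sequence, cfg: SimConfig
) -> tuple[Assembly, ErrorLedger]:
    """Degrade a truth sequence into a draft, recording every lesion.

    Lesions never overlap (collisions are resampled) and keep clear of the
    region's first and last kilobase, where read coverage tapers. Gap
    N-run lengths are recorded with a U(0.5, 1.5) length-estimation error so
    the resizing stage has real work; exact-20-bp gaps duplicate a 20-40 bp
    flank overlap around the Ns, mirroring the assembler convention.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = len(truth)
    margin = 1000
    taken: list[tuple[int, int]] = []

    def claim(a: int, b: int, pad: int = 25) -> bool:
        if a < margin or b > L - margin:
            return False
        for ta, tb in taken:
            if a - pad < tb and ta < b + pad:
                return False
        taken.append((a, b))
        return True

    ledger = ErrorLedger()
    n20 = int(round(cfg.exact20_fraction * cfg.gap_count))
    n_regular = cfg.gap_count - n20
    for _ in range(n_regular):
        for _attempt in range(1000):
            glen = int(rng.integers(cfg.gap_len_min, cfg.gap_len_max + 1))
            a = int(rng.integers(margin, L - margin - glen))
            if claim(a, a + glen):
                break
        else:
            raise RuntimeError("could not place gap without collision")
        n_len = max(2, int(round(glen * rng.uniform(0.5, 1.5))))
        ledger.records.append(Lesion("gap", a, a + glen, payload=str(n_len)))
    for _ in range(n20):
        for _attempt in range(1000):
            overlap = int(rng.integers(20, 41))
            p = int(rng.integers(margin, L - margin - overlap))
            if claim(p, p + overlap):
                break
        else:
            raise RuntimeError("could not place 20-bp convention gap")
        ledger.records.append(Lesion("gap20", p, p, payload=str(overlap)))

    n_sub = int(round(cfg.substitution_error_rate * L / 1000))
    for _ in range(n_sub):
        for _attempt in range(1000):
            p = int(rng.integers(margin, L - margin))
            if claim(p, p + 1, pad=5):
                break
        else:
            raise RuntimeError("could not place substitution")
        old = truth.residues[p]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        ledger.records.append(Lesion("substitution", p, p + 1, payload=f"{old}>{new}"))

    n_hp = int(round(cfg.homopolymer_indel_rate * L / 1000))
    runs = [
        (m.start(), m.end())
        for m in _HP_RUN.finditer(truth.residues)
        if margin < m.start() and m.end() < L - margin
    ]
    rng.shuffle(runs)
    placed = 0
    for a, b in runs:
        if placed >= n_hp:
            break
        if not claim(a, b, pad=10):
            continue
        run_len = b - a
        base = truth.residues[a]
        delta = int(rng.integers(1, 4))
        if rng.random() < 0.5 and run_len - delta >= 1:
            new_len, kind = run_len - delta, "hp_deletion"
        else:
            new_len, kind = run_len + delta, "hp_insertion"
        ledger.records.append(Lesion(kind, a, b, payload=f"{base}:{new_len}"))
        placed += 1
    # fewer eligible runs than requested events is fine; the ledger holds truth

    for _ in range(cfg.redundant_contig_count):
        for _attempt in range(1000):
            clen = int(rng.integers(1000, 3001))
            a = int(rng.integers(0, L - clen))
            ok = all(not (a < tb and ta < a + clen) for ta, tb in taken)
            if ok:
                break
        else:
            raise RuntimeError("could not place redundant contig")
        copy = _mutate(rng, truth.residues[a : a + clen],
                       rng.uniform(0, cfg.redundant_divergence_max))
        ledger.records.append(
            Lesion("redundant_contig", a, a + clen, payload=copy)
        )

    ledger.records.sort(key=lambda r: (r.kind == "redundant_contig", r.truth_start))
    draft = ledger.replay(truth)
    return draft, ledger


def simulate_read_pairs(truth: Sequence, cfg: SimConfig) -> ReadPairSet:
    """Simulate innie-oriented paired-end reads from the truth sequence.

    Insert sizes follow a normal distribution truncated to
    [insert_min, insert_max]; fragment starts are uniform; per-base errors
    are substitutions at ``base_error_rate``. Read ids embed the true
    fragment coordinates (``pair_<i>:<start>:<end>``) for mapping evaluation.
    Base qualities are a constant Q40.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    L = len(truth)
    if L <= cfg.insert_max:
        raise ValueError("truth shorter than insert_max")
    rl = cfg.read_len
    n_pairs = int(round(cfg.coverage * L / (2 * rl)))
    # insert_mean is the target *realized* mean: solve for the location of
    # the underlying normal, since asymmetric truncation shifts the mean
    from scipy.optimize import brentq

    def mean_gap(loc: float) -> float:
        a = (cfg.insert_min - loc) / cfg.insert_sd
        b = (cfg.insert_max - loc) / cfg.insert_sd
        return truncnorm.mean(a, b, loc=loc, scale=cfg.insert_sd) - cfg.insert_mean

    loc = brentq(mean_gap, cfg.insert_min, cfg.insert_max, xtol=1e-6)
    a = (cfg.insert_min - loc) / cfg.insert_sd
    b = (cfg.insert_max - loc) / cfg.insert_sd
    inserts = truncnorm.rvs(
        a, b, loc=loc, scale=cfg.insert_sd, size=n_pairs, random_state=rng
    ).round().astype(int)
    inserts = np.clip(inserts, cfg.insert_min, cfg.insert_max)
    starts = rng.integers(0, L - inserts + 1)
    qual = chr(40 + 33) * rl
    err_p = cfg.base_error_rate

    def seq_with_errors(s: str) -> str:
        if err_p <= 0:
            return s
        hits = np.flatnonzero(rng.random(len(s)) < err_p)
        if len(hits) == 0:
            return s
        ls = list(s)
        for i in hits:
            ls[i] = str(rng.choice([c for c in "ACGT" if c != ls[i]]))
        return "".join(ls)

    pairs = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag_end = s + ins
        r1 = seq_with_errors(truth.residues[s : s + rl])
        r2 = seq_with_errors(revcomp(truth.residues[frag_end - rl : frag_end]))
        pairs.append(ReadPair(f"pair_{i}:{s}:{frag_end}", r1, qual, r2, qual))
    return ReadPairSet(pairs, rl, cfg.insert_mean, cfg.insert_min, cfg.insert_max)


def write_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        for k, v in asdict(cfg).items():
            fh.write(f"{k}={v}\n")


def read_config(path) -> SimConfig:
    kwargs = {}
    fields = {f.name: f.type for f in SimConfig.__dataclass_fields__.values()}
    types = {f.name: type(getattr(SimConfig(), f.name)) for f in SimConfig.__dataclass_fields__.values()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = line.split("=", 1)
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = types[k](v)
    return SimConfig(**kwargs)
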