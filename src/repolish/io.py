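"""Readers and writers for the standard formats the pipeline touches.

FASTA, FASTQ (phred+33), GFF3 and VCF 4.2 are supported in the lossless
subset the pipeline uses. All internal coordinates are 0-based half-open;
conversion to the 1-based conventions of GFF3/VCF happens only here. FASTA
is emitted upper-case at 60 columns so outputs are byte-stable.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pysam
from Bio import SeqIO

from .model import (
    Assembly,
    GeneModel,
    MetricsReport,
    ReadPair,
    ReadPairSet,
    Sequence,
    Variant,
    has_n_stretch,
)

_VALID_DNA = set("ACGTN")


def _check_dna(seq: Sequence) -> None:
    bad = set(seq.residues) - _VALID_DNA
    if bad:
        pos = next(i for i, c in enumerate(seq.residues) if c in bad)
        raise ValueError(
            f"non-IUPAC-core character {seq.residues[pos]!r} in {seq.id} at position {pos}"
        )


def read_sequences(path: str | os.PathLike) -> list[Sequence]:
    """Read a FASTA file into upper-cased sequences, rejecting duplicate ids."""
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        s = Sequence(rec.id, str(rec.seq))
        _check_dna(s)
        seqs.append(s)
    return seqs


def read_fasta(
    path: str | os.PathLike, scaffold_ids: set[str] | None = None
) -> Assembly:
    """Read FASTA into an Assembly.

    Sequences carrying any N-run of length > 1 are classified as scaffolds,
    the rest as contigs; ``scaffold_ids`` overrides the classification.
    """
    scaffolds, contigs = [], []
    for s in read_sequences(path):
        if scaffold_ids is not None:
            (scaffolds if s.id in scaffold_ids else contigs).append(s)
        elif has_n_stretch(s.residues, 2):
            scaffolds.append(s)
        else:
            contigs.append(s)
    return Assembly(scaffolds=scaffolds, contigs=contigs, provenance=str(path))


def write_fasta(seqs: Iterable[Sequence] | Assembly, path: str | os.PathLike) -> None:
    if isinstance(seqs, Assembly):
        seqs = seqs.sequences()
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS) from GFF3."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        cds = []
        for f in db.children(gene, featuretype="exon"):
            exons.append((f.start - 1, f.end))
        for f in db.children(gene, featuretype="CDS"):
            cds.append((f.start - 1, f.end))
        attrs = gene.attributes
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                exons=sorted(exons),
                cds=sorted(cds),
                class_label=attrs.get("class_label", [None])[0],
                partial=attrs.get("partial", ["false"])[0] == "true",
            )
        )
    models.sort(key=lambda m: (m.seq_id, m.start, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.seq_id, m.start, m.gene_id)):
            attrs = f"ID={m.gene_id}"
            if m.class_label:
                attrs += f";class_label={m.class_label}"
            if m.partial:
                attrs += ";partial=true"
            fh.write(
                f"{m.seq_id}\trepolish\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.seq_id}\trepolish\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.seq_id}\trepolish\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # phase computed in translation order
            order = m.cds if m.strand == "+" else m.cds[::-1]
            phase = 0
            phases = {}
            for a, b in order:
                phases[(a, b)] = phase
                phase = (3 - ((b - a) - phase) % 3) % 3
            for i, (a, b) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.seq_id}\trepolish\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t"
                    f"{phases[(a, b)]}\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF 4.2

_VCF_HEADER = """##fileformat=VCFv4.2
##source=repolish
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    records: Iterable[Variant],
    refs: dict[str, str],
    path: str | os.PathLike,
    sample: str = "sample",
) -> None:
    """Emit variants as VCF 4.2, anchoring indel alleles per the standard."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for sid, seq in refs.items():
            fh.write(f"##contig=<ID={sid},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in sorted(records, key=lambda v: (v.seq_id, v.pos)):
            seq = refs[v.seq_id]
            if v.type == "snp":
                pos1, ref, alt = v.pos + 1, v.ref, v.alt
            elif v.type == "ins":
                anchor = seq[v.pos - 1]
                pos1, ref, alt = v.pos, anchor, anchor + v.alt
            else:  # del
                anchor = seq[v.pos - 1]
                pos1, ref, alt = v.pos, anchor + v.ref, anchor
            gt = "1/1" if v.zygosity == "homo" else "0/1"
            fh.write(
                f"{v.seq_id}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"DP={v.depth};AF={v.alt_fraction!r}\tGT\t{gt}\n"
            )


def read_vcf(path: str | os.PathLike) -> list[Variant]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            sample = rec.samples[0] if rec.samples else None
            gt = sample["GT"] if sample else (1, 1)
            zyg = "homo" if gt == (1, 1) else "hetero"
            depth = int(rec.info.get("DP", 0))
            # htslib stores INFO floats in single precision; recover the
            # written decimal value
            af = round(float(rec.info.get("AF", 0.0)), 6)
            if len(ref) == 1 and len(alt) == 1:
                v = Variant(rec.chrom, rec.pos - 1, ref, alt, "snp", zyg, depth, af)
            elif len(alt) > len(ref) and alt.startswith(ref):
                v = Variant(
                    rec.chrom, rec.pos - 1 + len(ref), "", alt[len(ref) :],
                    "ins", zyg, depth, af,
                )
            elif len(ref) > len(alt) and ref.startswith(alt):
                v = Variant(
                    rec.chrom, rec.pos - 1 + len(alt), ref[len(alt) :], "",
                    "del", zyg, depth, af,
                )
            else:
                raise ValueError(f"unsupported allele pair {ref}->{alt} at {rec.pos}")
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq_pairs(
    path1: str | os.PathLike,
    path2: str | os.PathLike,
    read_len: int = 152,
    insert_mean: float = 509.0,
    insert_min: int = 152,
    insert_max: int = 645,
) -> ReadPairSet:
    """Read two mated FASTQ files; record counts must match."""
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError(f"mate count mismatch: {len(r1)} vs {len(r2)} records")
    pairs = []
    for a, b in zip(r1, r2):
        qa = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qb = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(ReadPair(a.id.removesuffix("/1"), str(a.seq).upper(), qa,
                              str(b.seq).upper(), qb))
    return ReadPairSet(pairs, read_len, insert_mean, insert_min, insert_max)


def write_fastq_pairs(
    reads: ReadPairSet, path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in reads.pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_metrics_tsv(report: MetricsReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in report.as_rows():
            fh.write(f"{name}\t{value}\n")
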