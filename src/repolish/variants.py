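"""Variant calling from pileups, density metrics, and effect classification.

Calls SNPs and short indels against a refined reference with a base-quality
floor of Q20 and a depth ceiling (the mpileup/varFilter conventions),
computes changes/kb over regions, classifies each variant's consequence on
gene models (exon/intron/splice-site regions; missense, nonsense, silent,
frameshift, in-frame coding effects using the standard genetic code), and
exports per-window SNP density tracks across multiple read sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .model import Assembly, EffectRecord, GeneModel, Variant, revcomp
from .pileup import Pileup

SPLICE_SITE_WIDTH = 2  # canonical GT/AG intron positions


@dataclass
class CallStats:
    n_emitted: int = 0
    n_depth_filtered: int = 0  # sites above the depth ceiling


def call_variants(
    pileup: Pileup,
    min_base_q: int = 20,  # applied when the pileup was built
    min_depth: int = 3,
    max_depth: int = 42,
    hom_frac: float = 0.85,
    min_alt_frac: float = 0.2,
    stats: CallStats | None = None,
) -> list[Variant]:
    """Call SNPs and 1-3 bp indels from a pileup.

    Sites are emitted when the alternate fraction is at least
    ``min_alt_frac`` and depth lies in [min_depth, max_depth]; the depth
    ceiling suppresses collapsed-repeat pileups. Zygosity is homozygous at
    alternate fraction >= ``hom_frac``, heterozygous below.
    """
    out: list[Variant] = []
    stats = stats if stats is not None else CallStats()
    for seq_id, counts in pileup.counts.items():
        ref = pileup.refs[seq_id]
        depth = counts.sum(axis=0)
        ref_idx = np.array(
            ["ACGTN".index(b) if b in "ACGTN" else 4 for b in ref], dtype=np.int8
        )
        acgt = counts[:4].copy()
        cols = np.arange(acgt.shape[1])
        valid = ref_idx < 4
        acgt[ref_idx[valid], cols[valid]] = 0
        alt_counts = acgt.max(axis=0)
        alt_rows = acgt.argmax(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
        candidate = (depth >= min_depth) & (frac >= min_alt_frac) & (ref_idx < 4)
        stats.n_depth_filtered += int(np.sum(candidate & (depth > max_depth)))
        hits = np.flatnonzero(candidate & (depth <= max_depth))
        for p in hits:
            f = float(frac[p])
            out.append(
                Variant(
                    seq_id, int(p), ref[p], "ACGT"[alt_rows[p]], "snp",
                    "homo" if f >= hom_frac else "hetero", int(depth[p]), round(f, 4),
                )
            )
        for (pos, allele), n in pileup.insertions[seq_id].items():
            spanning = pileup.spanning_depth(seq_id, pos - 5, pos + 5)
            if spanning < min_depth:
                continue
            if spanning > max_depth:
                stats.n_depth_filtered += 1
                continue
            f = n / spanning
            if f >= min_alt_frac:
                out.append(
                    Variant(seq_id, pos, "", allele, "ins",
                            "homo" if f >= hom_frac else "hetero", spanning, round(f, 4))
                )
        for (a, b), n in pileup.deletions[seq_id].items():
            spanning = pileup.spanning_depth(seq_id, a - 5, b + 5)
            if spanning < min_depth:
                continue
            if spanning > max_depth:
                stats.n_depth_filtered += 1
                continue
            f = n / spanning
            if f >= min_alt_frac:
                out.append(
                    Variant(seq_id, a, ref[a:b], "", "del",
                            "homo" if f >= hom_frac else "hetero", spanning, round(f, 4))
                )
    out.sort(key=lambda v: (v.seq_id, v.pos))
    stats.n_emitted = len(out)
    return out


def changes_per_kb(variants: list[Variant], region: tuple[int, int]) -> float:
    """Variants per kilobase over a half-open region, to two decimals."""
    a, b = region
    if b <= a:
        raise ValueError("region length must be positive")
    n = sum(1 for v in variants if a <= v.pos < b)
    return round(1000.0 * n / (b - a), 2)


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (strand-aware)."""
    off = 0
    for a, b in model.cds:
        if a <= pos < b:
            plus_off = off + (pos - a)
            total = sum(e - s for s, e in model.cds)
            return plus_off if model.strand == "+" else total - 1 - plus_off
        off += b - a
    return None


def classify_variant_effect(
    v: Variant, models: list[GeneModel], genome: dict[str, str]
) -> list[EffectRecord]:
    """Classify a variant's consequence on every gene model it overlaps.

    Region is exon/intron/splice_site by interval overlap (splice sites are
    the first and last two intron bases); CDS SNPs are translated ref vs alt
    with the standard genetic code honoring strand (stop gain = nonsense,
    amino-acid change = missense, same residue = silent); CDS indels are
    frameshift when length % 3 != 0, else in-frame. Variants overlapping no
    gene yield a single intergenic record.
    """
    seq = genome.get(v.seq_id)
    if seq is None or v.pos >= len(seq) or v.pos < 0:
        raise ValueError(f"variant at {v.seq_id}:{v.pos} beyond sequence end")
    span = (v.pos, v.pos + max(1, len(v.ref)))
    records: list[EffectRecord] = []
    for m in models:
        if m.seq_id != v.seq_id or span[1] <= m.start or span[0] >= m.end:
            continue
        region = "intron"
        for a, b in m.introns():
            if a <= v.pos < b:
                if v.pos < a + SPLICE_SITE_WIDTH or v.pos >= b - SPLICE_SITE_WIDTH:
                    region = "splice_site"
                break
        else:
            if any(a <= v.pos < b for a, b in m.exons):
                region = "exon"
        consequence, aa_change = "n/a", ""
        in_cds = any(a <= v.pos < b for a, b in m.cds)
        if region == "exon" and in_cds:
            if v.type == "snp":
                off = _cds_offset(m, v.pos)
                cds = m.cds_sequence(seq)
                ci = off // 3
                codon = cds[ci * 3 : ci * 3 + 3]
                if len(codon) == 3:
                    alt_base = v.alt if m.strand == "+" else revcomp(v.alt)
                    k = off % 3
                    alt_codon = codon[:k] + alt_base + codon[k + 1 :]
                    aa_ref = _translate_codon(codon)
                    aa_alt = _translate_codon(alt_codon)
                    if aa_alt == aa_ref:
                        consequence = "silent"
                    elif aa_alt == "*":
                        consequence = "nonsense"
                    else:
                        consequence = "missense"
                    aa_change = f"{aa_ref}{ci + 1}{aa_alt}"
            else:
                indel_len = len(v.ref) or len(v.alt)
                consequence = "frameshift" if indel_len % 3 else "inframe"
        records.append(EffectRecord(v, m.gene_id, region, consequence, aa_change))
    if not records:
        records.append(EffectRecord(v, "", "intergenic", "n/a"))
    return records


def effects_table(records: list[EffectRecord]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": r.variant.seq_id,
            "pos": r.variant.pos,
            "type": r.variant.type,
            "zygosity": r.variant.zygosity,
            "gene_id": r.gene_id,
            "region": r.region,
            "consequence": r.consequence,
            "aa_change": r.aa_change,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def effect_summary(records: list[EffectRecord]) -> dict[str, int]:
    """Counts in the report vocabulary (Missense/Nonsense/Silent/Exons/...)."""
    out = {
        "Missense": 0, "Nonsense": 0, "Silent": 0,
        "Exons": 0, "Introns": 0, "Splice sites": 0, "Intergenic": 0,
    }
    for r in records:
        if r.region == "exon":
            out["Exons"] += 1
        elif r.region == "intron":
            out["Introns"] += 1
        elif r.region == "splice_site":
            out["Splice sites"] += 1
        else:
            out["Intergenic"] += 1
        if r.consequence == "missense":
            out["Missense"] += 1
        elif r.consequence == "nonsense":
            out["Nonsense"] += 1
        elif r.consequence == "silent":
            out["Silent"] += 1
    return out


def snp_density_track(
    variant_sets: dict[str, list[Variant]],
    window: int,
    seq_len: int,
    seq_id: str,
    reference_cultivar: str | None = None,
) -> pd.DataFrame:
    """Per-window variant counts per cultivar, with allele-sharing classes.

    For every variant the sharing class against the reference cultivar's
    sequence is ``alternative_two_alleles`` for a homozygous alternate and
    ``alternative_one_allele`` for a heterozygote; windows also count
    ``same`` positions where a cultivar matches the reference while another
    cultivar varies there.
    """
    all_sites: dict[int, set[str]] = {}
    for cultivar, vs in variant_sets.items():
        for v in vs:
            if v.seq_id == seq_id:
                all_sites.setdefault(v.pos, set()).add(cultivar)
    rows = []
    n_windows = (seq_len + window - 1) // window
    for cultivar, vs in variant_sets.items():
        own = {v.pos: v for v in vs if v.seq_id == seq_id}
        counts = np.zeros(n_windows, dtype=int)
        two_allele = np.zeros(n_windows, dtype=int)
        one_allele = np.zeros(n_windows, dtype=int)
        same = np.zeros(n_windows, dtype=int)
        for pos, who in all_sites.items():
            w = pos // window
            v = own.get(pos)
            if v is None:
                same[w] += 1
            else:
                counts[w] += 1
                if v.zygosity == "homo":
                    two_allele[w] += 1
                else:
                    one_allele[w] += 1
        for w in range(n_windows):
            rows.append(
                {
                    "seq_id": seq_id,
                    "start": w * window,
                    "end": min((w + 1) * window, seq_len),
                    "cultivar": cultivar,
                    "count": int(counts[w]),
                    "alternative_two_alleles": int(two_allele[w]),
                    "alternative_one_allele": int(one_allele[w]),
                    "same": int(same[w]),
                }
            )
    return pd.DataFrame(rows)
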