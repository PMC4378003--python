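"""Variant calling, densities, and effect classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from repolish.model import Assembly, GeneModel, Sequence, Variant
from repolish.pileup import Pileup
from repolish.variants import (
    CallStats,
    call_variants,
    changes_per_kb,
    classify_variant_effect,
    effect_summary,
    snp_density_track,
)


def _pileup_with_column(ref: str, pos: int, counts: dict) -> Pileup:
    pile = Pileup(Assembly(contigs=[Sequence("s", ref)]))
    for b, n in counts.items():
        row = "ACGTN".index(b)
        pile.counts["s"][row, pos] = n
    return pile


class TestCallVariants:
    def test_unanimous_alt_is_homozygous(self):
        pile = _pileup_with_column("ACGTACGT" * 4, 5, {"T": 20})
        (v,) = call_variants(pile)
        assert (v.pos, v.ref, v.alt, v.zygosity) == (5, "C", "T", "homo")

    def test_half_alt_is_heterozygous(self):
        pile = _pileup_with_column("ACGTACGT" * 4, 5, {"T": 10, "C": 10})
        (v,) = call_variants(pile)
        assert v.zygosity == "hetero"
        assert v.alt_fraction == 0.5

    def test_depth_ceiling_suppresses_site(self):
        pile = _pileup_with_column("ACGTACGT" * 4, 5, {"T": 60})
        stats = CallStats()
        assert call_variants(pile, max_depth=42, stats=stats) == []
        assert stats.n_depth_filtered == 1

    def test_low_fraction_not_called(self):
        pile = _pileup_with_column("ACGTACGT" * 4, 5, {"C": 18, "T": 2})
        assert call_variants(pile) == []  # 10% < 20% call threshold


class TestChangesPerKb:
    def test_r_gene_region_arithmetic(self):
        # 3,085 variants over positions 5,478,521-6,236,414 of a scaffold
        region = (5_478_521, 6_236_414)
        rng = np.random.default_rng(0)
        pos = rng.choice(np.arange(*region), size=3085, replace=False)
        vs = [Variant("s3", int(p), "A", "T", "snp", "homo", 10, 1.0) for p in pos]
        assert changes_per_kb(vs, region) == 4.07

    def test_improved_region_arithmetic(self):
        region = (5_478_926, 6_186_068)
        rng = np.random.default_rng(1)
        pos = rng.choice(np.arange(*region), size=180, replace=False)
        vs = [Variant("s3", int(p), "A", "T", "snp", "homo", 10, 1.0) for p in pos]
        assert changes_per_kb(vs, region) == 0.25

    def test_empty_region(self):
        assert changes_per_kb([], (0, 1000)) == 0.0
        with pytest.raises(ValueError):
            changes_per_kb([], (10, 10))


def _simple_gene(strand="+"):
    #          0123456789012345678901234567890
    # exon1 = 3..15, intron 15..25, exon2 25..34 (CDS spans both exons)
    genome = {"g": "TTTATGTGGGCTAAGTACTTTTTCAGGTTCTAAT" + "A" * 20}
    m = GeneModel("gene", "g", strand, exons=[(3, 15), (25, 34)], cds=[(3, 15), (25, 34)])
    return genome, m


class TestEffectClassification:
    def test_stop_gain_is_nonsense(self):
        genome, m = _simple_gene()
        # codon 2 is TGG (Trp); TGG->TGA at third codon position
        v = Variant("g", 8, "G", "A", "snp", "homo", 10, 1.0)
        (rec,) = classify_variant_effect(v, [m], genome)
        assert rec.region == "exon"
        assert rec.consequence == "nonsense"
        assert rec.aa_change == "W2*"

    def test_synonymous_is_silent(self):
        genome, m = _simple_gene()
        # codon 3 GCT (Ala) -> GCC (Ala)
        v = Variant("g", 11, "T", "C", "snp", "homo", 10, 1.0)
        (rec,) = classify_variant_effect(v, [m], genome)
        assert rec.consequence == "silent"

    def test_intron_edge_is_splice_site(self):
        genome, m = _simple_gene()
        for pos, expected in [(15, "splice_site"), (16, "splice_site"),
                              (17, "intron"), (23, "splice_site"), (20, "intron")]:
            v = Variant("g", pos, genome["g"][pos], "A" if genome["g"][pos] != "A" else "C",
                        "snp", "homo", 10, 1.0)
            (rec,) = classify_variant_effect(v, [m], genome)
            assert rec.region == expected, pos

    def test_cds_indel_frameshift_vs_inframe(self):
        genome, m = _simple_gene()
        fs = Variant("g", 6, "", "TT", "ins", "homo", 10, 1.0)
        inf = Variant("g", 6, "TGG", "", "del", "homo", 10, 1.0)
        assert classify_variant_effect(fs, [m], genome)[0].consequence == "frameshift"
        assert classify_variant_effect(inf, [m], genome)[0].consequence == "inframe"

    def test_intergenic_and_bounds(self):
        genome, m = _simple_gene()
        v = Variant("g", 40, "A", "T", "snp", "homo", 10, 1.0)
        (rec,) = classify_variant_effect(v, [m], genome)
        assert rec.region == "intergenic"
        with pytest.raises(ValueError, match="beyond"):
            classify_variant_effect(
                Variant("g", 10_000, "A", "T", "snp", "homo", 10, 1.0), [m], genome
            )

    def test_every_variant_counted_once_per_gene_context(self):
        genome, m = _simple_gene()
        m2 = GeneModel("gene2", "g", "+", exons=[(3, 15)], cds=[(3, 15)], partial=True)
        variants = [
            Variant("g", p, genome["g"][p], "A" if genome["g"][p] != "A" else "C",
                    "snp", "homo", 10, 1.0)
            for p in [5, 10, 20, 40]
        ]
        records = [r for v in variants for r in classify_variant_effect(v, [m, m2], genome)]
        s = effect_summary(records)
        # positions 5 and 10 hit both genes, 20 is intronic in gene 1 only,
        # 40 is intergenic: 4 + 1 + 1 = 6 records
        assert len(records) == 6
        assert s["Exons"] == 4 and s["Introns"] == 1 and s["Intergenic"] == 1


def _random_gene_fixture(rng):
    """A random multi-exon gene and a random CDS SNP, either strand."""
    strand = rng.choice(["+", "-"])
    n_exons = int(rng.integers(1, 4))
    pos = 10
    exons = []
    cds_len = 0
    for _ in range(n_exons):
        elen = int(rng.integers(2, 5)) * 3
        exons.append((pos, pos + elen))
        cds_len += elen
        pos += elen + int(rng.integers(8, 15))
    genome_len = pos + 10
    genome = "".join(rng.choice(list("ACGT"), genome_len))
    m = GeneModel("g", "chr", strand, exons=list(exons), cds=list(exons))
    cds_positions = [p for a, b in exons for p in range(a, b)]
    vpos = int(rng.choice(cds_positions))
    ref = genome[vpos]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    v = Variant("chr", vpos, ref, alt, "snp", "homo", 10, 1.0)
    return genome, m, v


def brute_force_consequence(genome: str, m: GeneModel, v: Variant) -> str:
    """Oracle: mutate the genome, retranslate the whole CDS, diff proteins."""
    mutated = genome[: v.pos] + v.alt + genome[v.pos + 1 :]
    before = str(Seq(m.cds_sequence(genome)).translate())
    after = str(Seq(m.cds_sequence(mutated)).translate())
    if after == before:
        return "silent"
    diffs = [(a, b) for a, b in zip(before, after) if a != b]
    if any(b == "*" for _, b in diffs):
        return "nonsense"
    return "missense"


class TestEffectOracle:
    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            genome, m, v = _random_gene_fixture(rng)
            (rec,) = classify_variant_effect(v, [m], {"chr": genome})
            assert rec.consequence == brute_force_consequence(genome, m, v), (
                m.strand, v,
            )


class TestDensityTrack:
    def test_empty_sets(self):
        df = snp_density_track({"cv": []}, window=1000, seq_len=3000, seq_id="s")
        assert (df["count"] == 0).all()
        assert len(df) == 3

    def test_counts_in_single_window(self):
        vs = [Variant("s", 100 + i, "A", "T", "snp", "homo", 9, 1.0) for i in range(10)]
        df = snp_density_track({"cv": vs}, window=1000, seq_len=3000, seq_id="s")
        by_win = df.set_index("start")["count"]
        assert by_win[0] == 10 and by_win[1000] == 0 and by_win[2000] == 0

    def test_allele_sharing_classes(self):
        shared_homo = Variant("s", 50, "A", "T", "snp", "homo", 9, 1.0)
        het = Variant("s", 60, "A", "T", "snp", "hetero", 9, 0.5)
        sets = {"cv1": [shared_homo, het], "cv2": [shared_homo]}
        df = snp_density_track(sets, window=1000, seq_len=1000, seq_id="s")
        cv1 = df[df.cultivar == "cv1"].iloc[0]
        cv2 = df[df.cultivar == "cv2"].iloc[0]
        assert cv1["alternative_two_alleles"] == 1 and cv1["alternative_one_allele"] == 1
        assert cv2["alternative_two_alleles"] == 1
        assert cv2["same"] == 1  # cv2 matches the reference where cv1 varies
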