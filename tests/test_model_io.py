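"""Domain types, format round-trips, and assembly metrics."""

import pytest
from hypothesis import given, settings, strategies as st

from repolish.io import (
    read_fasta,
    read_fastq_pairs,
    read_gff3,
    read_vcf,
    write_fasta,
    write_gff3,
    write_vcf,
)
from repolish.model import (
    Assembly,
    GeneModel,
    Sequence,
    Variant,
    assembly_metrics,
    find_n_stretches,
)


class TestNStretches:
    @pytest.mark.parametrize(
        "residues,min_len,expected",
        [
            ("ACGT", 1, []),
            ("NNACGTNNNN", 1, [(0, 2), (6, 10)]),
            ("ANA", 2, []),
            ("ANA", 1, [(1, 2)]),
            ("NNNN", 1, [(0, 4)]),
        ],
    )
    def test_examples(self, residues, min_len, expected):
        runs = find_n_stretches(Sequence("s", residues), min_len=min_len)
        assert [(r.start, r.end) for r in runs] == expected

    @given(
        st.lists(
            st.tuples(st.sampled_from("AN"), st.integers(1, 9)),
            min_size=1, max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_run_length_encoding(self, rle):
        # collapse adjacent identical-symbol runs to make the RLE canonical
        canon = []
        for sym, n in rle:
            if canon and canon[-1][0] == sym:
                canon[-1] = (sym, canon[-1][1] + n)
            else:
                canon.append((sym, n))
        s = "".join(sym * n for sym, n in canon)
        expected = []
        pos = 0
        for sym, n in canon:
            if sym == "N":
                expected.append((pos, pos + n))
            pos += n
        runs = find_n_stretches(Sequence("s", s))
        assert [(r.start, r.end) for r in runs] == expected


class TestMetrics:
    def test_example_assembly(self):
        a = Assembly(
            scaffolds=[Sequence("s1", "ACGTNNNNACGT")],
            contigs=[Sequence("c1", "GGCC")],
        )
        m = assembly_metrics(a)
        assert m.total_len == 16
        assert m.n_count == 4
        assert m.n_stretches_gt1 == 1
        assert m.total_len_no_n == 12

    def test_exact20_counted(self):
        a = Assembly(scaffolds=[Sequence("s1", "AC" + "N" * 20 + "GT")])
        assert assembly_metrics(a).n_stretches_exact20 == 1

    @given(
        st.lists(
            st.text(alphabet="ACGTN", min_size=1, max_size=60), min_size=1, max_size=8
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_length_conservation(self, residues_list):
        scaffolds = [
            Sequence(f"s{i}", res)
            for i, res in enumerate(residues_list)
            if set(res) != {"N"}
        ]
        if not scaffolds:
            return
        m = assembly_metrics(Assembly(scaffolds=scaffolds))
        assert m.total_len == m.total_len_no_n + m.n_count
        assert m.scaffold_len + m.contig_len == m.total_len


class TestFasta:
    def test_classification_and_parsing(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nacgt\n>s1\nACGTNNNNACGT\n")
        a = read_fasta(p)
        assert [c.id for c in a.contigs] == ["c1"]
        assert a.contigs[0].residues == "ACGT"
        assert [s.id for s in a.scaffolds] == ["s1"]
        assert [(r.start, r.end) for r in find_n_stretches(a.scaffolds[0])] == [(4, 8)]

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nACGT\n>c1\nGGCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_bad_character_reported_with_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nACXGT\n")
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(p)

    def test_round_trip_byte_stable(self, tmp_path):
        seqs = [Sequence("x", "ACGT" * 40), Sequence("y", "ACGTN")]
        p1, p2 = tmp_path / "1.fasta", tmp_path / "2.fasta"
        write_fasta(seqs, p1)
        write_fasta(Assembly(contigs=read_fasta(p1).contigs,
                             scaffolds=read_fasta(p1).scaffolds), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "m.gff3"
        m = GeneModel("g1", "s1", "+", exons=[(10, 19)], cds=[(10, 19)])
        write_gff3([m], p)
        text = p.read_text()
        assert "\tCDS\t11\t19\t" in text  # 1-based closed on disk
        back = read_gff3(p)
        assert back[0].cds == [(10, 19)]
        assert back[0].strand == "+"

    def test_round_trip(self, tmp_path):
        models = [
            GeneModel("gA", "s1", "+", exons=[(5, 20), (30, 50)],
                      cds=[(8, 20), (30, 45)], class_label="TNL", partial=True),
            GeneModel("gB", "s1", "-", exons=[(100, 160)], cds=[(100, 160)]),
        ]
        p = tmp_path / "m.gff3"
        write_gff3(models, p)
        back = read_gff3(p)
        assert [(m.gene_id, m.strand, m.exons, m.cds, m.class_label) for m in models] == [
            (m.gene_id, m.strand, m.exons, m.cds, m.class_label) for m in back
        ]


class TestVcf:
    def test_round_trip_identity(self, tmp_path):
        refs = {"s1": "ACGTACGTACGTACGT"}
        variants = [
            Variant("s1", 3, "T", "G", "snp", "homo", 20, 1.0),
            Variant("s1", 5, "", "TT", "ins", "hetero", 12, 0.5),
            Variant("s1", 8, "GT", "", "del", "homo", 15, 0.9),
        ]
        p = tmp_path / "v.vcf"
        write_vcf(variants, refs, p)
        assert read_vcf(p) == variants


class TestFastqPairs:
    def test_mate_count_mismatch(self, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("".join(f"@p{i}/1\nACGT\n+\nIIII\n" for i in range(3)))
        r2.write_text("".join(f"@p{i}/2\nACGT\n+\nIIII\n" for i in range(4)))
        with pytest.raises(ValueError, match="mate count mismatch"):
            read_fastq_pairs(r1, r2)

    def test_round_trip(self, tmp_path, clean_sim):
        from repolish.io import write_fastq_pairs

        reads = clean_sim["reads"]
        p1, p2 = tmp_path / "1.fastq", tmp_path / "2.fastq"
        write_fastq_pairs(reads, p1, p2)
        back = read_fastq_pairs(p1, p2)
        assert len(back) == len(reads)
        assert back.pairs[0].seq1 == reads.pairs[0].seq1
        assert back.pairs[-1].qual2 == reads.pairs[-1].qual2
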