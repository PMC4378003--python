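"""Gap closing, convention-gap merging, resizing, terminal trimming."""

import numpy as np
import pytest

from repolish.gaps import (
    _ConsensusWalker,
    close_gaps,
    merge_convention_gaps,
    resize_n_stretches,
    trim_terminal_ns,
)
from repolish.model import Assembly, ReadPair, ReadPairSet, Sequence, revcomp
from repolish.simulate import (
    SimConfig,
    degrade_assembly,
    generate_truth_region,
    simulate_read_pairs,
)
from conftest import small_config


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestCloseGaps:
    def test_unique_gap_closed_exactly(self):
        cfg = small_config(
            gap_count=2, exact20_fraction=0.0, substitution_error_rate=0.0,
            homopolymer_indel_rate=0.0, redundant_contig_count=0,
            base_error_rate=0.0, seed=31,
        )
        truth, _, _ = generate_truth_region(cfg)
        draft, ledger = degrade_assembly(truth, cfg)
        reads = simulate_read_pairs(truth, cfg)
        refined, report = close_gaps(draft, reads)
        assert all(t.status == "closed" for t in report.tasks)
        assert refined.scaffolds[0].residues == truth.residues
        for task, les in zip(
            sorted(report.tasks, key=lambda t: t.orig_start),
            sorted(ledger.of_kind("gap"), key=lambda l: l.draft_start),
        ):
            expected = truth.residues[
                les.truth_start : les.truth_end + task.consumed_right
            ]
            assert task.inserted == expected

    def test_no_gaps_is_a_noop(self, clean_sim):
        refined, report = close_gaps(clean_sim["draft"], clean_sim["reads"])
        assert report.tasks == []
        assert refined.scaffolds[0].residues == clean_sim["draft"].scaffolds[0].residues

    def test_closed_gaps_contain_no_n(self, small_sim):
        refined, report = close_gaps(small_sim["draft"], small_sim["reads"])
        for t in report.closed():
            assert "N" not in t.inserted

    def test_sequences_without_anchor_segment_skipped(self):
        a = Assembly(scaffolds=[Sequence("tiny", "ACGT" * 20 + "NNNN" + "ACGT" * 20)])
        reads = ReadPairSet([], 152, 509.0, 152, 645)
        refined, report = close_gaps(a, reads, min_anchor=300)
        assert report.skipped_sequences == ["tiny"]
        assert refined.scaffolds[0].residues == a.scaffolds[0].residues


class TestConsensusWalker:
    def test_branching_pool_stops_repeat_ambiguous(self):
        rng = np.random.default_rng(41)
        stem = _rand(rng, 60)
        contA, contB = _rand(rng, 60), _rand(rng, 60)
        pool = [stem + contA] * 5 + [stem + contB] * 5
        walker = _ConsensusWalker(pool, k=31)
        ext, reason = walker.extend(stem[:40], 100)
        assert reason == "repeat-ambiguous"
        assert len(ext) <= 60 - 40 + 1

    def test_clean_pool_extends_to_consensus(self):
        rng = np.random.default_rng(42)
        stem = _rand(rng, 200)
        pool = [stem[i : i + 100] for i in range(0, 100, 7)]
        walker = _ConsensusWalker(pool, k=31)
        ext, reason = walker.extend(stem[:50], 100)
        assert stem[50 : 50 + len(ext)] == ext
        assert len(ext) > 20


class TestMergeConventionGaps:
    def _fixture(self, overlap=22, mismatches=0):
        rng = np.random.default_rng(43)
        truth = _rand(rng, 3000)
        p = 1500
        dup = list(truth[p : p + overlap])
        for i in range(mismatches):
            j = 3 * i + 1
            dup[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[dup[j]]
        draft = truth[: p + overlap] + "N" * 20 + "".join(dup) + truth[p + overlap :]
        # draft: ...[true overlap][20 Ns][duplicated overlap copy]...
        return truth, Assembly(scaffolds=[Sequence("s", draft)])

    def test_true_overlap_merged_to_truth(self):
        truth, a = self._fixture()
        merged, report = merge_convention_gaps(a)
        assert report.tasks[0].status == "merged"
        assert merged.scaffolds[0].residues == truth

    def test_no_overlap_untouched(self):
        rng = np.random.default_rng(44)
        seq = _rand(rng, 2000) + "N" * 20 + _rand(rng, 2000)
        a = Assembly(scaffolds=[Sequence("s", seq)])
        merged, report = merge_convention_gaps(a)
        assert report.tasks[0].status == "open"
        assert merged.scaffolds[0].residues == seq

    def test_excess_mismatches_block_merge(self):
        _, a = self._fixture(overlap=22, mismatches=3)  # 3/22 > 2%
        merged, report = merge_convention_gaps(a)
        assert report.tasks[0].status == "open"

    def test_only_exact_twenty_runs_considered(self):
        rng = np.random.default_rng(45)
        seq = _rand(rng, 1000) + "N" * 21 + _rand(rng, 1000)
        _, report = merge_convention_gaps(Assembly(scaffolds=[Sequence("s", seq)]))
        assert report.tasks == []


class TestResize:
    def _fixed_insert_reads(self, truth, insert=509, rl=152, step=9):
        pairs = []
        for i, s in enumerate(range(0, len(truth) - insert, step)):
            frag = truth[s : s + insert]
            if "N" in frag[:rl] or "N" in frag[-rl:]:
                continue
            pairs.append(
                ReadPair(f"p{i}:{s}:{s + insert}", frag[:rl], "I" * rl,
                         revcomp(frag[-rl:]), "I" * rl)
            )
        return ReadPairSet(pairs, rl, float(insert), insert, insert)

    def test_estimator_arithmetic(self):
        # every spanning pair covers 409 bp outside the gap -> resized to 100
        rng = np.random.default_rng(46)
        truth = _rand(rng, 6000)
        true_gap = 100
        draft = truth[:3000] + "N" * 37 + truth[3000 + true_gap :]
        a = Assembly(scaffolds=[Sequence("s", draft)])
        reads = self._fixed_insert_reads(truth)
        resized, report = resize_n_stretches(a, reads)
        task = [t for t in report.tasks if t.status == "resized"][0]
        assert task.end - task.start == true_gap
        assert "N" * true_gap in resized.scaffolds[0].residues

    def test_no_spanning_pairs_keeps_length(self):
        rng = np.random.default_rng(47)
        seq = _rand(rng, 2000) + "N" * 50 + _rand(rng, 2000)
        a = Assembly(scaffolds=[Sequence("s", seq)])
        resized, report = resize_n_stretches(a, ReadPairSet([], 152, 509.0, 152, 645))
        assert report.tasks[0].status == "open"
        assert resized.scaffolds[0].residues == seq

    def test_negative_estimate_clamped_and_flagged(self):
        # gap recorded where the flanks are truly adjacent and inserts run long
        rng = np.random.default_rng(48)
        truth = _rand(rng, 6000)
        draft = truth[:3000] + "N" * 80 + truth[3000:]  # true distance 0
        a = Assembly(scaffolds=[Sequence("s", draft)])
        reads = self._fixed_insert_reads(truth)
        resized, report = resize_n_stretches(a, reads)
        task = report.tasks[0]
        assert task.status == "resized"
        assert task.note == "merge-candidate"
        assert task.end - task.start == 2


class TestTrimTerminalNs:
    @pytest.mark.parametrize(
        "residues,expected",
        [("NNNACGTNN", "ACGT"), ("ACGTNNAC", "ACGTNNAC"), ("NACGTN", "ACGT")],
    )
    def test_trimming(self, residues, expected):
        a = Assembly(scaffolds=[Sequence("s", residues)])
        out, dropped = trim_terminal_ns(a)
        assert out.sequences()[0].residues == expected
        assert dropped == []

    def test_all_n_sequence_removed_and_listed(self):
        a = Assembly(
            scaffolds=[Sequence("allN", "N" * 30), Sequence("keep", "ACGTNNGG")]
        )
        out, dropped = trim_terminal_ns(a)
        assert dropped == ["allN"]
        assert [s.id for s in out.sequences()] == ["keep"]
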