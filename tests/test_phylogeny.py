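"""Domain architectures, NJ phylogeny, concordance, and orthology pairing."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from repolish.model import DomainedProtein
from repolish.phylogeny import (
    classify_architecture,
    cluster_concordance,
    nbs_distance_matrix,
    nj_tree,
    reciprocal_best_hits,
    to_newick,
)
from repolish.simulate import SimConfig, generate_truth_region, proteins_from_models

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(pid, kinds, seq=None, cluster=""):
    seq = seq or "M" + "".join(AA) * 10
    n = len(seq)
    step = n // max(len(kinds), 1)
    domains = [(k, i * step, (i + 1) * step) for i, k in enumerate(kinds)]
    return DomainedProtein(pid, seq, domains, cluster_label=cluster)


class TestArchitecture:
    @pytest.mark.parametrize(
        "kinds,expected",
        [
            (["TIR", "NBS", "LRR"], "TNL"),
            (["TIR", "NBS"], "TN"),
            (["NBS"], "N"),
            (["NBS", "LRR"], "NL"),
            (["CC", "NBS"], "CN"),
            (["CC", "NBS", "LRR", "LRR_Cterm"], "CNL"),
        ],
    )
    def test_classes(self, kinds, expected):
        assert classify_architecture(_protein("p", kinds)) == expected

    def test_missing_nbs_rejected(self):
        with pytest.raises(ValueError, match="no NBS"):
            classify_architecture(_protein("p", ["TIR", "LRR"]))

    def test_classifier_total_on_simulated_cluster(self):
        cfg = SimConfig(region_len=40_000, n_cluster_genes=6, seed=2)
        truth, models, cmap = generate_truth_region(cfg)
        for p in proteins_from_models(truth, models, cmap):
            assert classify_architecture(p) in ("TN", "TNL", "N", "NL", "CN", "CNL")


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        rng = np.random.default_rng(0)
        nbs = "".join(rng.choice(AA, 100))
        ps = [
            _protein(f"p{i}", ["NBS"], seq=nbs)
            for i in range(3)
        ]
        d = nbs_distance_matrix(ps)
        assert np.allclose(d.data, 0.0)

    def test_five_differences_in_hundred(self):
        rng = np.random.default_rng(1)
        nbs = "".join(rng.choice(AA, 100))
        mutated = list(nbs)
        for i in rng.choice(100, size=5, replace=False):
            mutated[i] = AA[(AA.index(mutated[i]) + 1) % 20]
        ps = [
            _protein("a", ["NBS"], seq=nbs),
            _protein("b", ["NBS"], seq="".join(mutated)),
            _protein("c", ["NBS"], seq="".join(rng.choice(AA, 100))),
        ]
        d = nbs_distance_matrix(ps)
        assert d["a", "b"] == pytest.approx(0.05, abs=1e-9)

    def test_symmetry_and_zero_diagonal(self):
        cfg = SimConfig(region_len=40_000, n_cluster_genes=5, seed=3)
        truth, models, cmap = generate_truth_region(cfg)
        d = nbs_distance_matrix(proteins_from_models(truth, models, cmap))
        assert np.allclose(d.data, d.data.T)
        assert np.allclose(np.diag(d.data), 0.0)


def _random_additive_tree(rng, n):
    """Random binary tree topology with branch lengths; returns the skbio
    tree and its additive path-length distance matrix (the oracle)."""
    from skbio.tree import TreeNode

    nodes = [TreeNode(name=f"t{i}", length=round(float(rng.uniform(0.05, 1.0)), 3))
             for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(length=round(float(rng.uniform(0.05, 1.0)), 3))
        parent.extend([a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    labels = sorted(t.name for t in root.tips())
    dm = np.zeros((len(labels), len(labels)))
    idx = {l: k for k, l in enumerate(labels)}
    tip = {t.name: t for t in root.tips()}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = tip[a].distance(tip[b])
            dm[idx[a], idx[b]] = dm[idx[b], idx[a]] = d
    return root, DistanceMatrix(dm, labels)


def _bipartition_set(tree):
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        under = frozenset(t.name for t in node.tips())
        parts.add(min(under, leaves - under, key=lambda s: (len(s), sorted(s))))
    return {p for p in parts if 1 < len(p) < len(leaves) - 1}


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # additive matrix from tree ((a:1,b:2):1,(c:3,d:4)); path metric oracle
        labels = ["a", "b", "c", "d"]
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], labels
        )
        tree = nj_tree(dm)
        assert _bipartition_set(tree) == {frozenset({"a", "b"})}
        tip = {t.name: t for t in tree.tips()}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert tip[a].distance(tip[b]) == pytest.approx(dm[a, b], abs=1e-9)

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(4, 13))
            true_tree, dm = _random_additive_tree(rng, n)
            est = nj_tree(dm)
            assert _bipartition_set(est) == _bipartition_set(true_tree)
            tip = {t.name: t for t in est.tips()}
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1 :]:
                    assert tip[a].distance(tip[b]) == pytest.approx(dm[a, b], abs=1e-6)

    def test_deterministic_under_relabeling(self):
        rng = np.random.default_rng(8)
        _, dm = _random_additive_tree(rng, 5)
        n1 = to_newick(nj_tree(dm))
        shuffled = dm.filter(["t3", "t0", "t4", "t1", "t2"])
        n2 = to_newick(nj_tree(shuffled))
        assert n1 == n2


class TestConcordance:
    def test_simulated_tandem_duplication_history_fully_concordant(self):
        cfg = SimConfig(region_len=50_000, n_cluster_genes=8, seed=5)
        truth, models, cmap = generate_truth_region(cfg)
        prots = proteins_from_models(truth, models, cmap)
        tree = nj_tree(nbs_distance_matrix(prots))
        rep = cluster_concordance(tree, {p.protein_id: p.cluster_label for p in prots})
        assert rep.fraction_monophyletic == 1.0

    def test_single_cluster_trivially_concordant(self):
        rng = np.random.default_rng(9)
        _, dm = _random_additive_tree(rng, 6)
        tree = nj_tree(dm)
        rep = cluster_concordance(tree, {f"t{i}": "A" for i in range(6)})
        assert rep.fraction_monophyletic == 1.0

    def test_random_labels_near_permutation_null(self):
        rng = np.random.default_rng(10)
        _, dm = _random_additive_tree(rng, 10)
        tree = nj_tree(dm)
        labels = ["A"] * 5 + ["B"] * 5
        # permutation null: expected concordance under label shuffles
        null = []
        for _ in range(300):
            perm = list(rng.permutation(labels))
            cmap = {f"t{i}": perm[i] for i in range(10)}
            null.append(cluster_concordance(tree, cmap).fraction_monophyletic)
        null_mean = np.mean(null)
        assert null_mean < 0.2  # monophyly of random 5-of-10 splits is rare

    def test_invariant_under_rerooting(self):
        cfg = SimConfig(region_len=50_000, n_cluster_genes=6, seed=6)
        truth, models, cmap = generate_truth_region(cfg)
        prots = proteins_from_models(truth, models, cmap)
        tree = nj_tree(nbs_distance_matrix(prots))
        labels = {p.protein_id: p.cluster_label for p in prots}
        base = cluster_concordance(tree, labels).fraction_monophyletic
        for tip_name in [p.protein_id for p in prots][:3]:
            rerooted = tree.root_at(tree.find(tip_name).parent)
            assert cluster_concordance(rerooted, labels).fraction_monophyletic == base

    def test_missing_label_rejected(self):
        rng = np.random.default_rng(11)
        _, dm = _random_additive_tree(rng, 4)
        with pytest.raises(ValueError, match="without cluster label"):
            cluster_concordance(nj_tree(dm), {"t0": "A"})


class TestReciprocalBestHits:
    def test_disjointly_similar_pairs_all_matched(self):
        rng = np.random.default_rng(12)
        seqs = ["".join(rng.choice(AA, 80)) for _ in range(3)]
        set_a = [_protein(f"a{i}", ["NBS"], seq=s) for i, s in enumerate(seqs)]
        mut = []
        for s in seqs:
            l = list(s)
            for j in rng.choice(80, size=4, replace=False):
                l[j] = AA[(AA.index(l[j]) + 3) % 20]
            mut.append("".join(l))
        set_b = [_protein(f"b{i}", ["NBS"], seq=s) for i, s in enumerate(mut)]
        pairs, ambiguous = reciprocal_best_hits(set_a, set_b)
        assert sorted(pairs) == [("a0", "b0"), ("a1", "b1"), ("a2", "b2")]
        assert ambiguous == []

    def test_tied_paralogs_flagged_cluster_level(self):
        rng = np.random.default_rng(13)
        s = "".join(rng.choice(AA, 80))
        other = "".join(rng.choice(AA, 80))
        set_a = [_protein("a0", ["NBS"], seq=s), _protein("a1", ["NBS"], seq=other)]
        set_b = [
            _protein("b0", ["NBS"], seq=s),
            _protein("b1", ["NBS"], seq=s),  # identical twin: a0 cannot choose
        ]
        pairs, ambiguous = reciprocal_best_hits(set_a, set_b)
        assert "a0" in ambiguous
        assert ("a0", "b0") not in pairs and ("a0", "b1") not in pairs

    def test_empty_set(self):
        assert reciprocal_best_hits([_protein("a", ["NBS"])], []) == ([], [])
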