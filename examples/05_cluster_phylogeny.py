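"""NBS-domain phylogeny of a tandem-duplicated R-gene cluster.

Simulates a region whose genes arose by duplication within proximity
sub-clusters, classifies each protein's domain architecture, builds a
neighbor-joining tree over NBS-domain p-distances, and checks that the
genomic sub-clusters are monophyletic clades of the tree.
"""

from repolish import SimConfig
from repolish.phylogeny import (
    classify_architecture,
    cluster_concordance,
    nbs_distance_matrix,
    nj_tree,
    to_newick,
)
from repolish.simulate import generate_truth_region, proteins_from_models

cfg = SimConfig(region_len=60_000, n_cluster_genes=8, n_subclusters=4, seed=5)
truth, models, cluster_map = generate_truth_region(cfg)
proteins = proteins_from_models(truth, models, cluster_map)

for p in proteins:
    print(f"{p.protein_id}: sub-cluster {p.cluster_label}, "
          f"architecture {classify_architecture(p)}, {len(p.sequence)} aa")

dm = nbs_distance_matrix(proteins)
tree = nj_tree(dm)
report = cluster_concordance(tree, {p.protein_id: p.cluster_label for p in proteins})
print()
print("newick:", to_newick(tree)[:120], "...")
print("per-sub-cluster monophyly:", report.per_cluster)
print(f"concordance: {report.fraction_monophyletic:.2f}")
print()
print("A concordance of 1.0 means every genomic sub-cluster forms its own")
print("clade — the signature of local tandem amplification.")
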