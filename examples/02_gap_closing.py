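"""Close one unsequenced gap by anchored read extension.

Builds a 20-kb truth sequence, hides a 300-bp segment behind an N-stretch of
(deliberately wrong) recorded length, simulates reads from the truth, and
closes the gap. The inserted sequence is compared base-by-base to the hidden
truth segment.
"""

from repolish import SimConfig
from repolish.gaps import close_gaps
from repolish.model import Assembly, Sequence
from repolish.simulate import generate_truth_region, simulate_read_pairs

cfg = SimConfig(region_len=20_000, n_cluster_genes=2, n_subclusters=2, seed=7)
truth, _, _ = generate_truth_region(cfg)

a, b = 9_000, 9_300  # hide truth[9000:9300] behind 210 Ns (wrong length)
draft = Assembly(
    scaffolds=[Sequence("s1", truth.residues[:a] + "N" * 210 + truth.residues[b:])]
)
reads = simulate_read_pairs(truth, cfg)

refined, report = close_gaps(draft, reads)
(task,) = report.tasks
print(f"gap status: {task.status} after {task.iterations_used} iteration(s)")
print(f"inserted {len(task.inserted)} bp; truth segment is {b - a} bp")
print("inserted == truth segment:",
      task.inserted == truth.residues[a : b + task.consumed_right])
print()
print("The closer recruits pairs with one mate anchored in a gap flank and")
print("the mate dangling into the gap, then walks a k-mer consensus of the")
print("dangling mates from both flanks until the extensions overlap.")
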