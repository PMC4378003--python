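"""Simulate a degraded 30-kb cluster region, refine it, and score recovery.

Generates a truth region carrying a small tandem-duplicated R-gene cluster,
degrades it (gaps, substitution and homopolymer errors, redundant contigs),
simulates 30x 2x152 bp pairs, runs the full pipeline, and prints the
ground-truth recovery report.
"""

import json
import tempfile

from repolish import RunConfig, SimConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        sim=SimConfig(
            region_len=30_000, n_cluster_genes=4, n_subclusters=2,
            gap_count=6, redundant_contig_count=2, seed=42,
        ),
        outdir=tmp,
    )
    result = run_pipeline(cfg)

r = result.recovery
print(json.dumps(r.as_dict(), indent=1))
print()
print(f"Of {r.gaps_planted} planted gaps, {r.gaps_correctly_closed} were closed to")
print(f"the true sequence (recall {r.gap_recall:.2f}); {r.errors_corrected} of")
print(f"{r.errors_planted} planted base errors were corrected with")
print(f"{r.false_corrections} false corrections, and the draft's unknown (N)")
print(f"sequence dropped by {100 * r.n_reduction:.1f}%.")
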