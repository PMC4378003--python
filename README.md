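# repolish

Desk-scale refinement of gap- and error-ridden draft assembly regions from
paired-end resequencing reads, with downstream analyses of NBS-LRR
disease-resistance gene clusters.

## The problem

Plant NBS-LRR resistance genes occur in clusters of highly similar tandem
paralogs. Such regions assemble badly: drafts of R-gene clusters are riddled
with unsequenced gaps (N-stretches), isolated base-call errors, homopolymer
length errors, and redundant contigs — and the broken sequence in turn breaks
gene annotation (truncated ORFs, false stops, genes split in two). Before a
cluster's duplication history or its variation across cultivars can be
analyzed, the sequence itself has to be repaired.

`repolish` implements that repair strategy as a tested, deterministic
library, plus the analyses that follow it:

1. **Redundancy removal** — a contig is dropped when ≥ 99% of it aligns at
   ≥ 98% identity inside a strictly larger contig or any scaffold.
2. **Gap closing** — read pairs with one mate anchored in a gap flank and
   the other dangling gap-ward drive a k-mer consensus walk from both
   flanks, over up to six iterations; when the two extensions overlap, the
   gap is spliced closed. Exact-20-bp assembler gaps, whose flanks truly
   overlap by convention, are merged directly.
3. **Gap resizing** — surviving N-runs are re-estimated from insert-size
   evidence: new length = median over spanning pairs of
   (mean insert − bases covered outside the gap).
4. **Consensus correction** — reads are remapped each iteration and the
   reference is changed wherever **more than 75% of reads at a position with
   coverage ≥ 4** support one alternative (substitutions and 1–3 bp indels);
   iterated to a fixed point.
5. **Analyses** — variant calling (Q20 floor, depth ceiling 42) and
   changes/kb densities; variant effect classification on gene models
   (missense/nonsense/silent, exon/intron/splice-site, frameshift/in-frame);
   domain-architecture classes (TN, TNL, N, NL, CN, CNL); a neighbor-joining
   phylogeny of NBS domains and its concordance with genomic sub-clusters;
   reciprocal-best-hit orthology across species.

Every stage is verifiable by ground-truth recovery: the `simulate` module
generates truth regions carrying tandem-duplicated gene clusters, degrades
them into drafts while recording every lesion in a replayable ledger, and
simulates the read library (2×152 bp, insert 152–645 bp with mean 509).

## A worked example

```bash
python examples/01_end_to_end_refinement.py
```

simulates a 30-kb region (4-gene cluster, 6 gaps, substitution and
homopolymer errors, 2 redundant contigs, 30× reads), refines it, and prints:

```
Of 6 planted gaps, 6 were closed to
the true sequence (recall 1.00); 39 of
39 planted base errors were corrected with
0 false corrections, and the draft's unknown (N)
sequence dropped by 100.0%.
```

The other examples each demonstrate one capability: gap closing
(`02_gap_closing.py`), strict-majority correction
(`03_consensus_correction.py` — prints each applied record with its read
support), variant effects (`04_variant_effects.py`), and the cluster
phylogeny (`05_cluster_phylogeny.py`, which reports per-sub-cluster
monophyly and a concordance of 1.00 on a simulated tandem-duplication
history).

A thin CLI mirrors the library: `repolish simulate`, `repolish refine
redundancy|close-gaps|correct`, `repolish analyze variants|metrics`,
`repolish all`.

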