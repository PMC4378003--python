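# Methods

This note documents the models and procedures implemented in `repolish`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Scope and coordinates

The package targets *regions* — tens of kilobases to a few megabases — not
whole genomes; data structures and algorithms are chosen for clarity and
determinism at that scale (pure-Python k-mer indexes, edlib for alignment).
Internally every coordinate is 0-based half-open; GFF3 and VCF are converted
at the I/O boundary and nowhere else. FASTA output is upper-case at 60
columns so stage outputs are byte-stable and diffable.

An assembly is a set of *scaffolds* (sequences that may contain N-stretches,
i.e. maximal runs of uncertain nucleotides) and *contigs* (sequences with no
N-run longer than one base; single-N noise is tolerated). Classification on
load follows that rule and can be overridden.

## Synthetic data: what it emulates

`simulate.SimConfig` defaults define the study conditions used throughout
validation:

| parameter | default | meaning |
|---|---|---|
| `region_len` | 100 kb | truth region length |
| `n_cluster_genes` / `n_subclusters` | 8 / 4 | tandem R-gene mimics in proximity sub-clusters |
| `duplication_divergence` | 0.05 subs/site | within-sub-cluster paralog divergence |
| `gap_count` | 20 | planted gaps (25% exact-20-bp convention gaps) |
| `gap_len_min/max` | 50–500 bp | deleted truth segment per ordinary gap |
| `substitution_error_rate` | 1 /kb | isolated draft base errors |
| `homopolymer_indel_rate` | 0.3 /kb | ±1–3 bp errors, only on runs ≥ 4 |
| `redundant_contig_count` | 5 | truth copies at ≤ 1% divergence, 1–3 kb |
| `read_len`, `insert_mean/min/max` | 152; 509; 152–645 bp | the read library |
| `insert_sd` | 80 bp | spread of the truncated-normal insert |
| `coverage` | 30× | read depth |
| `base_error_rate` | 0.2% | per-base read substitution errors |

Choices worth flagging:

* **Gap-length estimation error.** A gap's recorded N-run length is the true
  deleted length × U(0.5, 1.5): draft N-lengths estimate genomic distances
  only loosely, which is exactly what gives the resizing stage work.
* **Exact-20-bp convention gaps** duplicate a 20–40 bp flank overlap around
  the Ns, reproducing the assembler convention that such gaps mark adjacent
  contigs which truly overlap.
* **Insert sizes** are drawn from a normal truncated to
  [`insert_min`, `insert_max`]; the location parameter is solved (Brent's
  method) so the *realized* mean equals `insert_mean` — naive truncation of
  N(509, 80) at 645 would shift the mean to ≈ 500.
* **Gene models are structural mimics**: 3 exons, 400 codons, valid splice
  dinucleotides, start/stop codons, hierarchical divergence (sub-cluster
  ancestors at 4× the within-cluster rate, so sub-clusters form clades of
  the duplication history). No attempt is made to mimic real TIR/NBS/LRR
  sequence content — downstream stages consume structure, not biology.
* **Per-base read error rate** (0.2%) is a generic short-read figure, not a
  measured one. Base qualities are a constant Q40; quality-floor behavior is
  exercised with constructed fixtures instead.
* **Reads are emitted already clean** — adapter/quality trimming is upstream
  of this package's scope.
* Lesions never overlap (collisions are resampled, never silently merged)
  and keep 1 kb clear of the region ends where coverage tapers. All draws
  come from one seeded generator in a documented order, so every output is
  reproducible from the config.

Because of these simplifications, passing recovery tests demonstrate the
*mechanics* of refinement — anchored extension, strict-majority pileup
consensus, containment detection, insert-based resizing — under realistic
coverage, error and divergence levels. They do not demonstrate robustness to
structural variation between read source and assembly, chimeric drafts,
non-uniform coverage, or base-quality pathologies, none of which the
generator produces.

## Read mapping

A k-mer seeded (k = 21), edlib-verified mapper places mates jointly:
seeds vote on diagonals, candidate loci are verified by banded infix
alignment, and a proper-pair combination (opposite strands, innie, insert
within bounds) is preferred over independent placement. Reads whose best
placement ties between distinct loci are left unplaced and counted as
ambiguous — repeat-derived reads must not vote in any consensus. The
placement edit-distance ceiling is 4% of read length.

## Gap refinement

*Convention gaps.* For N-runs of exactly 20 bp, the largest flank overlap of
≥ 20 bp at ≤ 2% mismatches is spliced (after trying up to 10 bp of end
trimming on either flank, the allowance for low-quality contig ends).

*Read-based closing* runs up to 6 iterations. Per iteration and open gap,
pairs with one mate anchored within one insert length of a flank and
oriented gap-ward are recruited; the dangling mates form the extension pool.
A greedy k-mer walk (k = 31 in the `small` profile, 61 in the `paper`
profile — 61-mers are too sparse to seed reliably at 30–100 kb test scale)
extends each flank by up to one read length per iteration; each base
requires ≥ 3 supporting reads and ≥ 75% agreement, echoing the strictness of
the manual correction rule; a second branch at ≥ 40% support stops the walk
as `repeat-ambiguous`. When the two extended flanks overlap by ≥ k with at
most one mismatch, the gap is spliced closed (an overlap reaching past the
extensions consumes duplicated flank bases — the convention-gap case);
otherwise the recorded N-run shrinks by the bases gained and the next
iteration continues. Closed inserts never contain N by construction.

*Resizing.* For each surviving N-run with ≥ 5 spanning pairs (mates anchored
on opposite flanks), the new length is the rounded median of
(mean insert − outside-gap span), clamped to [2, `insert_max`]; estimates
≤ 0 are clamped to 2 and flagged as merge candidates. Gaps with fewer
spanning pairs keep their recorded length.

Every stage records its interval replacements in a `CoordinateMap`, so
positions in the stage's input can be projected into its output — this is
how the evaluator matches planted lesions to applied repairs across the
whole pipeline.

## Consensus correction

Per iteration: remap, pile up (base-quality floor Q20 on substitution
counts), and apply the strict-majority rule — change a base iff depth ≥ 4
and the top non-reference allele exceeds 75% of the column, with `>` strict
at 75% and `≥` at depth 4 (both boundaries unit-tested). The analogous rule
corrects 1–3 bp insertions and deletions, with support counted over reads
fully spanning the event ± 5 bp (avoids edge artifacts) and indel events
left-normalized against the reference so homopolymer evidence accumulates at
one locus. Columns with intermediate alternate fractions (40–60%) are never
corrected, only logged: on a doubled-haploid source they indicate mapping
artifacts, not variants. Iteration stops when a pass makes no changes; a
proposed change that would exactly invert an earlier one freezes the
position (oscillation guard). The ledger reports both gross and net
(revert-adjusted) counts per corrected-error class, because whether
published corrected-error tallies include reverts is generally unknowable
from the reports of the tools that produce them. Convergence is checked as a
fixed point: re-running correction on corrected output must produce an empty
ledger.

## Redundancy filter

Candidates are found by 15-mer seeds with dust-style low-complexity masking
applied to seeds only (never to the identity computation); the query stride
is kept odd so seed positions sweep every residue class of the stride-4
container index. Verification uses edlib infix alignment; identity is exact
matches over aligned columns with N never counting as a match, and coverage
is the fraction of non-N query bases in aligned columns — identity is
computed over the covered portion, a documented choice where the alternative
(whole-query) is equally defensible. A contig is removed iff some strictly
larger contig or any scaffold contains it at coverage ≥ 0.99 and identity
≥ 0.98; equal-length identical contigs are both kept (no strictly larger
container exists) and logged as ties. The removal set is computed against
the unmodified assembly, making the operation order-independent and
idempotent; scaffolds are never removed.

## Variant calling and effects

Sites are emitted at alternate fraction ≥ 0.2 with depth in [3, 42]; the
ceiling suppresses collapsed-repeat pileups. Zygosity is homozygous at
alternate fraction ≥ 0.85. The 0.2 and 0.85 thresholds are declared,
configurable package choices (the tools this stage parallels bury them as
internals). Effects: splice sites are the first/last 2 intron bases (the
canonical GT/AG positions); coding SNPs are translated ref-vs-alt with the
standard genetic code honoring strand; CDS indels are frameshift iff length
mod 3 ≠ 0. A variant overlapping several genes yields one record per gene —
aggregation policy ("most severe") belongs in reports, not in the
classifier. The classifier is validated against a brute-force oracle that
mutates the genome, retranslates the entire CDS and diffs the proteins.

## Phylogeny and orthology

NBS-domain distances are p-distances (1 − identity over aligned columns,
terminal gaps excluded) from global BLOSUM62 alignments; the tree is
standard neighbor joining with labels canonicalized to sorted order for
deterministic tie-breaking, and negative NJ branch lengths clamped to zero.
This deliberately replaces multi-stage alignment-pipeline trees: at desk
scale, the quantity being tested — whether genomic proximity sub-clusters
are monophyletic — is robust to tree method, and no claims about branch
lengths are made anywhere. Monophyly on the unrooted tree means an edge
separates the cluster's leaves from all others; the concordance statistic is
the fraction of clusters of size ≥ 2 that are monophyletic, and is invariant
under re-rooting. Orthologs are reciprocal best hits by full-protein
identity; tied best hits (near-identical paralogs) leave the protein
unpaired, flagged as cluster-level orthology. Domain coordinates are inputs
(TSV), not computed.

## Pipeline and evaluation

Stage order is fixed — redundancy, convention-gap merge, read-based closing,
resizing, correction, terminal-N trim, analyses — though every stage is
independently callable; redundancy must precede mapping-based stages or
duplicate loci would siphon reads into ambiguity. Each stage's output FASTA
is retained, the effective configuration is echoed into the run directory,
stages checkpoint their state for resume, and reruns under the same seed are
byte-identical.

The evaluator scores recovery against the simulation ledger: a gap counts as
correctly closed when the content now occupying the original N-run interval
matches the deleted truth segment at ≥ 99.5% identity (flank bases consumed
by overlap splicing are accounted to the truth side as well); convention-gap
merges are checked by the junction continuing exactly as the truth does;
corrections are matched to planted lesions through the composed coordinate
maps of all preceding stages, including the indel shifts of correction
itself. Precision counts any unmatched correction as false. Redundant-contig
removal is scored by planted contig ids.

## Problem sizes used in validation

Unit tests run on 30-kb regions with 4-gene clusters; the recovery surface
runs five seeds of the full default conditions (100 kb, 20 gaps, 130 base
errors, 5 redundant contigs, 30×), about 20 seconds per seed on one CPU.
The effect-classifier oracle uses 1,000 random gene/variant fixtures on both
strands; tree recovery uses random additive trees of 4–12 taxa against the
generating tree's path metric.

## Known limitations

* The mapper, closer and filter are desk-scale by design; none is tuned for
  genome-scale inputs (≫ 5 Mb) or deep repeat structure beyond what the
  ambiguity guards handle.
* Gap closing does not assemble unanchored reads de novo and never joins
  different scaffolds.
* Correction handles events ≤ 3 bp; longer events are the gap machinery's
  domain.
* The effect vocabulary covers the CDS-centric classes only (no UTR or
  regulatory annotation), and variant calling is single-sample, without
  joint genotype likelihoods.
* The assembly metrics report carries Ns, stretch counts and their ratio;
  published "average N-stretch size" figures computed with other divisors
  are not reproduced.
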