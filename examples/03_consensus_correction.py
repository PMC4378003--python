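"""Correct substitution and homopolymer errors by strict read majority.

Plants one substitution and one homopolymer length error in a small draft,
then corrects them from simulated reads. A change requires more than 75% of
reads at a position (at depth >= 4) to support the same alternative — the
strictness appropriate for a doubled-haploid source, where true
disagreements are near-unanimous.
"""

import numpy as np

from repolish.correct import correct_consensus
from repolish.model import Assembly, ReadPair, ReadPairSet, Sequence, revcomp

rng = np.random.default_rng(3)
flank = lambda n: "".join(rng.choice(list("ACGT"), n)).replace("AAAA", "ACGA")
truth = flank(3_000) + "A" * 9 + flank(3_000)

draft_seq = list(truth.replace("A" * 9, "A" * 11))  # homopolymer 9 -> 11
draft_seq[1_500] = "G" if draft_seq[1_500] != "G" else "C"  # one substitution
draft = Assembly(contigs=[Sequence("region", "".join(draft_seq))])

pairs = [
    ReadPair(f"p{i}:{s}:{s + 400}", truth[s : s + 152], "I" * 152,
             revcomp(truth[s + 248 : s + 400]), "I" * 152)
    for i, s in enumerate(range(0, len(truth) - 400, 10))
]
reads = ReadPairSet(pairs, 152, 400.0, 400, 400)

corrected, ledger = correct_consensus(draft, reads)
for r in ledger.records:
    print(f"iteration {r.iteration}: {r.kind} at {r.pos}: "
          f"{r.before!r} -> {r.after!r} ({r.support_fraction:.0%} of {r.depth} reads)")
print("corrected sequence equals truth:", corrected.contigs[0].residues == truth)
print("corrected-error classes:", ledger.gross_counts())
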