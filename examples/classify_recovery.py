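"""Classify RNAPC alleles and score how a founder's descendants recovered.

Builds a founder clone fixed for the RpoB-1272 adaptation and three
kinds of descendants: one that lost the allele (reversion), one that
kept it and gained a secondary RNAPC mutation (compensation), and one
that simply kept it (retained).
"""

from ltsp_recovery.classify import classify_outcome, classify_rnapc, frequency_table
from ltsp_recovery.mutations import CloneGenotype, Mutation


def clone(cid, cycle, muts):
    return CloneGenotype(cid, "2", 127, cycle, frozenset(muts))


anrnapc = Mutation(4_181_245, "C", "T", "rpoB", "nonsynonymous", aa_position=1272)
comp = Mutation(4_188_923, "T", "G", "rpoC", "nonsynonymous", aa_position=1075)
passenger = Mutation(50_000, "G", "A", "yaaB", "synonymous", aa_position=12)

founder = clone("2_1", 0, [anrnapc, passenger])
reverted = clone("2_1_r", 16, [passenger])
compensated = clone("2_1_c", 16, [anrnapc, passenger, comp])
retained = clone("2_1_k", 16, [anrnapc, passenger])

for c in (founder, reverted, compensated, retained):
    print(f"{c.clone_id:<8} category={classify_rnapc(c):<18} "
          f"outcome={classify_outcome(founder, c)}")

print()
print("category frequencies by cycle (percent of sequenced clones):")
for cycle, row in frequency_table([founder, reverted, compensated, retained]).items():
    print(f"  cycle {cycle:>2}: " + ", ".join(f"{k}={v:.0f}%" for k, v in row.items()))
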