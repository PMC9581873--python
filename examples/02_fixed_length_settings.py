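"""The six fixed-length strategies on a toy corpus.

Shows how padding/truncation to corpus statistics and the positional
sub-sequence settings each map variable-length sequences to one common
length.
"""

from botnet.length_policy import (
    CorpusLengthStats,
    LengthPolicy,
    Strategy,
    apply_policy,
)

seqs = ["ACGUACGUACGU", "ACGUA", "ACGUACGUACGUACGUACGU"]  # lengths 12, 5, 20
stats = CorpusLengthStats.from_lengths([len(s) for s in seqs])
print(f"corpus lengths: min={stats.min_len} max={stats.max_len} mean={stats.mean_len:.2f}\n")

policies = [
    LengthPolicy(Strategy.MAX_PAD),            # pad everything to the max (20)
    LengthPolicy(Strategy.MIN_TRUNC),          # truncate everything to the min (5)
    LengthPolicy(Strategy.AVG_HYBRID),         # pad/trim to the rounded mean (12)
    LengthPolicy(Strategy.START, X=6),         # first 6 residues
    LengthPolicy(Strategy.END, Y=6),           # last 6 residues
    LengthPolicy(Strategy.START_END, X=4, Y=4),  # first 4 + last 4
]
for policy in policies:
    out = apply_policy(seqs, policy, stats)
    print(f"{policy.strategy.value:>12}: " + "  ".join(out))
# Note the 5-nt sequence under the sub-sequence settings: budgets larger
# than the sequence are end-padded with '-' so the fixed-length contract
# holds for every instance.
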