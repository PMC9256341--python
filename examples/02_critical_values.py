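"""Simulate upper percentile points of the null statistic.

Builds a small critical-value table at s = 0.4 and compares the 95% column
with the published reference table shipped in the package.
"""

import nbu2test as nt

sizes = [10, 20, 40, 80]
table = nt.build_table(0.4, sizes, n_reps=10_000, seed=1)
ref = nt.reference_critical_table(0.4)

print(table.to_tsv())
print("n   simulated q95   published q95")
for i, n in enumerate(sizes):
    print(f"{n:<4d}{table.values[i, 0]:<16.4f}{ref.lookup(n, 0.95):.4f}")
print("\nBoth columns shrink as n grows (the statistic concentrates at its")
print("null mean); differences are Monte-Carlo noise at 10,000 replicates.")
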