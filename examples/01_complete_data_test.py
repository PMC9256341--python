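"""Test two complete clinical datasets for NBU(2) aging.

The leukemia ages show strong aging (statistic far above the critical
value); the liver-cancer times look exponential (statistic below it).
"""

import nbu2test as nt

for name, s in [("leukemia", 0.4), ("leukemia", 0.6),
                ("liver_complete", 0.4), ("liver_complete", 0.6)]:
    sample = nt.load_dataset(name)
    res = nt.run_test(sample, nt.TestConfig(s=s, alpha=0.05, seed=7))
    print(f"{name:15s} s={s}: statistic={res.statistic:8.4f}  "
          f"crit={res.critical_value:.4f}  reject H0: {res.reject_h0}")

print("\nA rejection means the data age in the NBU(2) sense: a used unit is")
print("stochastically worse than a new one, so e.g. a treatment's benefit decays.")
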