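"""Pitman asymptotic efficiency of the test for the three alternative families.

PAE is the local drift slope of the statistic at the null scaled by the null
standard deviation: larger means the test detects small departures sooner.
"""

import nbu2test as nt

fams = [nt.lfr(0.0), nt.weibull(1.0), nt.makeham(0.0)]
print("family    s=0.4    s=0.6    PARE(0.4 vs 0.6)")
for fam in fams:
    p4, p6 = nt.pae(fam, 0.4), nt.pae(fam, 0.6)
    print(f"{fam.name:9s}{p4:<9.4f}{p6:<9.4f}{nt.pare(fam, 0.4, 0.6):.4f}")

print("\nThe Weibull direction is the easiest to detect locally, Makeham the")
print("hardest; the s=0.4/0.6 choice barely matters (PARE near 1).")
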