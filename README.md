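# nbu2test

A nonparametric test of **exponentiality against NBU(2) aging** for survival
data, complete or right-censored.

A lifetime distribution with survival function F̄ is *new better than used in
the increasing concave order*, X ∈ NBU(2), when

    ∫₀ˣ F̄(u + t) du  ≤  F̄(t) ∫₀ˣ F̄(u) du    for all x, t > 0,

i.e. a used item of age t is stochastically shorter-lived (in increasing
concave order) than a new one.  The exponential law is the memoryless
boundary of the class.  In treatment studies this distinction carries the
practical question: if post-treatment survival is NBU(2) rather than
exponential, the treatment's effect wears off with age, whereas exponential
survival means age has no effect.  The package is aimed at
biostatisticians and reliability analysts who need a formal level-α test of
H₀ "exponential" against H₁ "NBU(2), not exponential".

## The statistic

With φ(s) = E[e^(−sX)] the Laplace transform of the lifetime, the departure
measure

    δ(s) = (1/s³) [ s·E(X e^(−sX)) − φ(s)(1 − φ(s)) ]

is zero for every exponential law (any rate) and positive inside NBU(2).
Its empirical version is a U-type average of the kernel

    φ(Xᵢ, Xⱼ) = s Xᵢ e^(−sXᵢ) + e^(−sXᵢ) e^(−sXⱼ) − e^(−sXᵢ)

over **all ordered pairs** (i, j), diagonal included, divided by s³·n(n−1).
Large values reject H₀.  Critical values are simulated from unit-exponential
samples at the same n and s (s ∈ {0.4, 0.6} are the tabulated conventions);
an asymptotic-normal variant √n·s³·δ̂/σ₀(s) is also provided.  For
right-censored data a Kaplan–Meier plug-in version δ_c with its own simulated
critical values is included.  The package also ships Monte-Carlo power
estimation against linear-failure-rate (LFR), Weibull and Makeham
alternatives, and a Pitman-asymptotic-efficiency calculator.

## Worked example

Four classical oncology datasets ship with the package (`nbu2test.list_datasets()`):
40 leukemia patient ages (years), 39 liver-cancer survival times (days,
complete), the 51-patient censored liver-cancer series, and 61 censored
lung-cancer times (weeks).

```python
import nbu2test as nt

sample = nt.load_dataset("leukemia")                      # n = 40, ages in years
res = nt.run_test(sample, nt.TestConfig(s=0.4, alpha=0.05, seed=7))
print(res.summary())
```

prints

```
statistic      1.50416
s              0.4
n              40
critical value 0.218303 (alpha=0.05, simulated)
NBU(2) evidence: yes
```

The statistic δ̂(0.4) = 1.504 far exceeds the simulated 95% null point
0.218 at n = 40, so exponentiality is rejected: these leukemia survival
times show NBU(2) aging.  The same test on the complete liver-cancer data
gives δ̂(0.4) = 0.073, below the critical value — no evidence against
exponentiality there.  The same calls work from the shell:

```sh
nbu2 test --input leukemia.txt --s 0.4 --alpha 0.05 --seed 7
nbu2 crit --n 40 --s 0.4 --reps 10000 --seed 1
nbu2 power --family weibull --theta 4 --n 10 --seed 1
nbu2 pae --family lfr:0 --s 0.4
```

Short narrative scripts for each capability live in `examples/`.

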