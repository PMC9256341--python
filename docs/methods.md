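# Methods

## Model and hypotheses

Lifetimes X > 0 with survival function F̄ are tested for

* H₀: F is exponential (any rate) — the memoryless boundary of all aging
  classes;
* H₁: F ∈ NBU(2) \ {exponential} — ∫₀ˣ F̄(u+t) du ≤ F̄(t) ∫₀ˣ F̄(u) du for
  all x, t > 0 ("new better than used in the increasing concave order").

The class chain NBU ⊂ NBU(2) ⊂ NBUE places NBU(2) among the broad aging
classes, so a rejection is evidence of aging in a weak, widely applicable
sense.

## The departure measure and its estimator

Writing φ(s) = E[e^(−sX)] for the Laplace transform, the departure

    δ(s) = (1/s³) [ s·E(X e^(−sX)) − φ(s)(1 − φ(s)) ]

is exactly 0 for every exponential rate β (the identity
sβ/(β+s)² − (β/(β+s))·(s/(β+s)) = 0) and positive under NBU(2)
alternatives.  It is estimated by the kernel average

    δ̂(s) = (1/(s³ n(n−1))) Σᵢ Σⱼ [ s Xᵢ e^(−sXᵢ) + e^(−sXᵢ)e^(−sXⱼ) − e^(−sXᵢ) ]

with both indices running over **all** n observations — the diagonal i = j is
included, and the divisor stays n(n−1).  This convention is deliberate: it is
the one that reproduces the published worked examples and percentile tables
this implementation is validated against.  Its consequence is an exact
O(1/n) positive null mean,

    E₀[δ̂] = [ s/(1+s)² + 1/(1+2s) − 1/(1+s) ] / (s³ (n−1)),

which the test suite asserts; because critical values are simulated under
the identical convention, the test's size is unaffected.

The statistic is **not scale invariant**: data enter in their raw time
units and s (an inverse time) is applied directly, matching the published
applications (ages in years and times in days are both referred to the same
critical table).  δ̂(cX, s/c) = c³ δ̂(X, s) holds exactly and is property-
tested.

Numerics: all exponential arguments are ≤ 0, so there is no overflow.  The
O(n) reduced form n·Σ s Xᵢe^(−sXᵢ) + (Σ e^(−sXᵢ))·Σ(e^(−sXⱼ)−1) is used;
near the null the sum cancels almost completely, so the scalar path
accumulates the three partial sums exactly (`math.fsum`), keeping it within
~10⁻¹³ relative of an exact double loop.  The Monte-Carlo path uses plain
vectorised summation, whose error is orders of magnitude below simulation
noise.

## Asymptotics and the null variance

The projection of the kernel under H₀ is

    ξ(x) = s x e^(−sx) + ((1−s)/(1+s)) e^(−sx) − 1/(1+s)²,

with E₀[ξ] = 0, and √n·s³·(δ̂ − δ) → N(0, σ₀²) where σ₀² = Var₀[ξ(X)].
From the exponential moments E[e^(−asX)] = 1/(1+as),
E[X e^(−2sX)] = 1/(1+2s)², E[X² e^(−2sX)] = 2/(1+2s)³:

    σ₀² = 2s²/(1+2s)³ + 2s(1−s)/((1+s)(1+2s)²) + (1−s)²/((1+s)²(1+2s)) − 1/(1+s)⁴

(≈ 0.00242 at s = 0.4, 0.00542 at s = 0.6; verified against quadrature of
ξ²e^(−x) and against Monte Carlo).  The optional asymptotic calibration
rejects when √n·s³·δ̂/σ₀(s) > z₁₋α; simulated calibration is the default
and is what the validated reference numbers use.

## Monte-Carlo calibration

Critical values are upper empirical quantiles (numpy's default linear
interpolation between order statistics, "type 7" — the choice is far below
Monte-Carlo noise at 10⁴ replicates) of δ̂ over unit-exponential samples,
simulated at the same n and s, 10,000 replicates by default.  Rate 1 is the
conventional null; the tabulated magnitudes confirm it.  Lookups off a
pre-built grid interpolate linearly in n; simulating on demand at the exact
n is the default (accuracy over speed — a 10⁴-replicate simulation at
n ≤ 100 takes well under a second).  All randomness flows through
`numpy.random.Generator` objects seeded explicitly; grids spawn one child
`SeedSequence` per cell, so tables are reproducible row by row.

A transcription of the published percentile table (s = 0.4 and 0.6,
n = 5(5)100) ships as a fixture for regression comparison only; our
simulated points agree with its 95% column to a few percent, consistent with
the ~0.003 quantile standard error both simulations carry at 10⁴
replicates.

## Censored data

For right-censored samples Z₍₁₎ ≤ … ≤ Z₍ₗ₎ with indicators d, the statistic

    δ_c = (1/(s³ l(l−1))) [ s η̂ − θ̂ (1 − θ̂) ]

uses the one-at-a-time Kaplan–Meier factors C_k = (l−k)/(l−k+1):

* θ̂ = Σ_m e^(−sZ₍ₘ₎) [Π_{p≤m−2} C_p^{d_p} − Π_{p≤m−1} C_p^{d_p}] — a KM
  plug-in for φ(s); the brackets telescope into KM point masses (shifted by
  one index, as published; the first observation's mass is dropped, an
  O(1/l) effect);
* η̂ = Σ_j [Π_{k≤j−1} C_k^{d_k}] (Z₍ⱼ₎ − Z₍ⱼ₋₁₎) — the area under the KM
  curve, i.e. the restricted mean lifetime.

Empty products are 1; ties order events before censorings.  The running
product Π C_p^{d_p} equals the standard Kaplan–Meier survival estimate
(verified against lifelines on random tie-free samples to 10⁻¹²).

Two structural caveats are inherited from the statistic as published and are
deliberately preserved: the η̂ term estimates E[X] rather than E[X e^(−sX)],
so δ_c centres at s²(2+s)/((1+s)² s³ l(l−1)) > 0 under H₀ rather than at 0;
and the extra 1/(l(l−1)) factor shrinks it by two orders of magnitude
relative to the complete-data statistic.  Both cancel out of the decision
because critical values are simulated from δ_c itself under exponential
lifetimes (optionally with independent exponential censoring at a user-set
rate; the default is none, since no mechanism is specified for the published
censored table).  The published censored percentile table ships as a
reference fixture only: its generating mechanism is not reconstructible (its
entries sit below the null centre of δ_c as defined), and the published
censored worked-example values (~10¹⁴–10⁷⁰) are unreachable from a formula
whose every term is bounded by max(Z); neither is used for validation.

## Alternative families

| family  | survival | null | cumulative-hazard inversion |
|---------|----------|------|------------------------------|
| LFR     | e^(−x−θx²/2) | θ=0 | x = (−1+√(1+2θE))/θ, closed form |
| Weibull | e^(−x^θ)     | θ=1 | x = E^(1/θ), closed form |
| Makeham | e^(−x−θ(x+e^(−x)−1)) | θ=0 | bisection on [E/(1+θ), E], 100 iterations (~10⁻³⁰ interval), residual < 10⁻¹² |

Samplers draw E ~ Exp(1) and invert H(x) = E; goodness of fit is tested at
deciles against the analytic survival (n = 50,000, max deviation < 0.01).

## Pitman asymptotic efficiency

PAE is defined at the kernel level: with
μ(θ) = s·E_θ[X e^(−sX)] − φ_θ(s)(1−φ_θ(s)),

    PAE = |μ′(θ₀)| / σ₀(s),
    μ′(θ₀) = s² [ (2/(1+s)) ∫ e^(−sx) G(x) dx − ∫ x e^(−sx) G(x) dx ],

where G = ∂F̄/∂θ at the null: −(x²/2)e^(−x) (LFR), −x·ln(x)·e^(−x)
(Weibull), −(x+e^(−x)−1)e^(−x) (Makeham).  Integrals use adaptive
quadrature split at x = 1 (the Weibull integrand's ln x changes sign there;
x ln x → 0 at 0 so the integrals converge absolutely).  Closed forms used as
cross-checks: μ′(θ₀) = s²/(1+s)⁴ for LFR and
∫e^(−sx)G = −1/((1+s)²(2+s)) for Makeham; a finite-difference oracle on
μ(θ) validates all three families.  This self-consistent definition is the
package's own: the formula could not be reconciled with any published
per-family efficiency figures, so those figures are not validation targets
here.  Ratios of PAEs across s (or, with the same σ₀ convention, across
tests) give Pitman relative efficiencies.

## Power study

Power against a family at (θ, n, α, s) is the proportion of family samples
whose statistic exceeds the simulated null critical value at the same
(n, s, α).  Defaults: α = 0.05, s = 0.4 (the published power table does not
state its s; both 0.4 and 0.6 are accepted conventions), 10,000 replicates.
The critical value is simulated once per sample size; `crit_reps` lets the
threshold use more replicates than the power loop, because at n = 10 the
threshold's quantile error (worth ~0.01 of power at 10⁴ replicates)
dominates the binomial error that `mc_se` reports.  Independent child
streams are spawned per cell from the master seed.

What the study conditions imply: at raw scale, LFR and Makeham lifetimes
shrink toward 0 as θ grows while s stays fixed, so their finite-n power
*decreases* in θ and stays near zero at n = 10 even though their population
departure is positive — their departure (≈0.05–0.11) sits an order of
magnitude below the n = 10 critical value (≈0.22–0.53).  Only for Weibull
(power ≈0.88 at θ = 4, n = 10) is the n = 10 study informative.
Monotonicity of power is therefore property-tested in n for all families
and in θ for Weibull.

## Synthetic data and what the tests show

All simulation inputs are generated internally: unit-exponential nulls and
the three parametric alternatives above.  These emulate i.i.d. lifetime
sampling with (optionally) independent exponential right censoring.  They do
not emulate covariate structure, dependent or informative censoring, ties
from coarse measurement, or model misspecification outside the three
families — so a passing suite certifies the statistic, its calibration and
its power under the stated sampling models, not behaviour on arbitrary
registry data.  The four packaged clinical datasets (40 leukemia ages; 39
complete and 51 censored liver-cancer times; 61 censored lung-cancer times)
are transcribed exactly as published, including one duplicated value and one
out-of-order entry in the leukemia table — fidelity to the source over
tidiness.

## Tunable parameters

* `s` (> 0, inverse time): the transform parameter; 0.4 and 0.6 are the
  tabulated conventions.  Because the statistic is scale dependent, s should
  be chosen relative to the data's time unit.
* `alpha` ∈ (0,1): test level; default 0.05.
* `n_reps` (≥ 100): Monte-Carlo replicates; default 10,000.  Quantile SE at
  the 95% point is ≈ 0.003 statistic units at n = 40, s = 0.4.
* `crit_reps`: replicates behind power-study thresholds (default = n_reps).
* `censoring_rate` (> 0 or None): exponential censoring rate for censored
  null calibration; default None.

## Known limitations

* No standard errors or confidence intervals for δ̂ on real data; the
  package reports a decision at a fixed level.
* The censored statistic is implemented exactly as published, including its
  non-centred null and index-shifted KM masses; it self-calibrates but its
  published reference values cannot be cross-validated.
* Raw-scale power against scale-shrinking families (LFR, Makeham) at small
  n is intrinsically poor; users wanting scale-free behaviour should rescale
  their data (and s) deliberately rather than rely on the statistic.
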