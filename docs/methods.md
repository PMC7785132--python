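# Methods

## Model and data flow

Each patient belongs to one of *K* disjoint biomarker partitions and is
randomised (1:1 by default) between a control and an experimental arm.
Within partition *j* hazards are proportional with log hazard ratio θⱼ;
θⱼ < 0 means the experimental arm delays the event. All estimation is
based on log-rank score statistics: a snapshot of one partition's data at
calendar day *a* censors every subject at
min(event day, last follow-up, *a*) and yields the score
S = Σₜ (d_E − d·n_E/n) and information
V = Σₜ d·(n_E/n)(n_C/n)(n−d)/(n−1) over distinct event times, so that
θ̂ = S/V ~ N(θ, 1/V) asymptotically. A positive score means excess
experimental events. Subjects entering after *a* are excluded from the
snapshot, not treated as censored at time zero.

Three calendar times structure a trial: the interim *t₁* (day of the
prespecified interim event count), the final analysis *t₂* (day of the
prespecified stage-2 event count, determined by stage-2 patients only so
that the two stages stay independent), and *t̃₁ = t₁ + δ* with δ a
prespecified follow-up extension for stage-1 patients without events at
the interim. The combined summary (S_N, V_N) pools stage-1 patients
censored at *t̃₁* with stage-2 patients censored at *t₂* in a single
log-rank analysis; the increment (S_N − S₁, V_N − V₁) is asymptotically
independent of the interim score (independent increments), and the naive
estimator θ̂_N = S_N/V_N coincides algebraically with the
inverse-variance combination of θ̂₁ and θ̂₂. Setting δ = 0 freezes the
stage-1 data at the interim; the simulator evaluates every estimator both
ways because the extension trades a small approximation error in the
independence assumption for a uniformly smaller RMSE.

## Selection rules and truncation bounds

Two interim rules are implemented behind one dispatch surface. The
*adaptive threshold* (prefix) rule assumes the partitions are ordered by
expected benefit and continues with the largest prefix {1..s} whose
prevalence-weighted mean interim estimate is ≤ b; s = 0 stops the trial.
The *independent* rule keeps every partition with θ̂₁ⱼ ≤ b. Boundary
ties select (the inequality is read inclusively); a stop is encoded as an
empty selected set, which downstream estimation refuses.

Conditioning on the selection is equivalent to confining θ̂₁ⱼ, given the
other partitions' interim estimates, to a truncation interval (lⱼ, wⱼ]:
for the prefix rule wⱼ = (p'ₛb − Σ_{i≤s,i≠j} pᵢθ̂₁ᵢ)/pⱼ and
lⱼ = max_{m=s+1..K} (p'ₘb − Σ_{i≤m,i≠j} pᵢθ̂₁ᵢ)/pⱼ (−∞ when everything
is selected); for the independent rule (−∞, b]. The defining property —
substituting any interior value reproduces the selection, any exterior
value changes it — is verified by grid search in the test suite.

## The conditionally unbiased estimator

Conditional on the selection, the increment θ̂₂ⱼ is unbiased for θⱼ, and
Rao-Blackwellising it against the complete sufficient statistic gives the
UMVCUE. The computation reduces to a truncated normal mean: given θ̂_N,
the interim estimate is N(θ̂_N, s²) with s = σ₁²/√(σ₁²+σ₂²), free of θ,
and the selection truncates it to (l, w). Writing m for the mean of that
truncated normal,

θ̂_U = θ̂_N − (σ₂²/σ₁²)(m − θ̂_N)
     = θ̂_N − σ₂²/√(σ₁²+σ₂²) · [φ(g(l)) − φ(g(w))]/[Φ(g(l)) − Φ(g(w))],
g(x) = √(σ₁²+σ₂²)/σ₁² · (θ̂_N − x).

The truncated-normal mean is evaluated with `scipy.stats.truncnorm`
(accurate in far tails, vectorised); with both bounds infinite the
correction is exactly zero, and a numerically degenerate truncation
region falls back to the naive estimate with a warning. A quadrature
oracle (numeric integration of the conditional density) pins the
implementation to 1e-8 in the tests, and a 100,000-replicate exact-normal
simulation confirms conditional unbiasedness under both rules.

The estimator is *decreasing* in each truncation bound: tightening a
bound from above concentrates the selection event on smaller interim
estimates, enlarging the upward correction. With δ = 0 the estimator is
an asymptotic UMVCUE; with δ > 0 the independent-increments assumption is
approximate and small residual biases can remain, which the simulation
study quantifies.

Known limitation, documented rather than matched: in the published
two-partition illustration, the partition-1 bias-adjusted values printed
under both rules are not reproducible from the printed inputs — at
w = 1.676 the truncation is ≈7.6 conditional standard deviations from
θ̂_N, forcing a correction of order 1e-13, yet a visible correction is
printed. The partition-2 values reproduce to all printed digits under
both rules, as does every other printed quantity, so the partition-1
entries are treated as a probable typesetting erratum.

## Closed testing and duality intervals

For hypothesis testing, evidence against the intersection hypothesis H_I
is summarised per stage by a Šidak adjustment of the pairwise one-sided
p-values, 1 − (1 − min_{i∈I} p_{k,i})^{|I|}; stage-1 pairwise p-values
use θ̃₁ⱼ (stage-1 patients at t̃₁ for selected partitions, at t₁ for
dropped ones unless they remain on follow-up), stage-2 p-values use
stage-2 patients only, computed on I ∩ 𝒮 with exponent |I ∩ 𝒮| and set
to 1 when that intersection is empty. Stages are combined with the
weighted inverse-normal function; the prespecified weights satisfy
ω₁² + ω₂² = 1 and default to the square roots of the stagewise shares of
the prespecified event total (1/√2 each for the benchmark design; the
configuration also accepts the shares themselves via `event_shares`).
The closure principle rejects H_j at one-sided level α/2 iff every
intersection containing j is rejected.

Confidence bounds invert the family of shifted-null tests. When every
selected partition's hypothesis is rejected, the lower bound solves
C(max{p_M⁺, 1−(1−p₁ⱼ(v))^K}, 1−(1−p₂ⱼ(v))^{|𝒮|}) = α/2 in the shift v,
clipped at zero, where p_M⁺ is the largest stage-1 intersection p-value
over the dropped partitions (zero when none are dropped). With mixed
conclusions, a rejected partition's bound is fixed at 0 — flagged
*non-informative*, a structural drawback of the procedure — and a
non-rejected partition's bound is the minimum over subsets I ∋ j of the
largest shift of coordinate j alone at which the subset's test still
accepts (+∞ for subsets already rejected at the null). Upper bounds
apply the identical machinery to the sign-flipped data and negate the
result, which makes the upper/lower anti-symmetry exact by construction.

Numerics: the combined p-value C(v) is nondecreasing in the shift, so
each bound is found by Brent root finding to 1e-6 on a bracket of ±10
interim standard errors, expanded to ±20 before declaring failure; a
subset whose test still accepts at +20 standard errors is non-binding
(+∞). p-values are clamped to [1e-15, 1−1e-15] before the normal
quantile, with both-extreme inputs mapping to 0 or 1. Subset enumeration
is over all 2^K − 1 nonempty subsets, guarded at K ≤ 15.

## Simulator

The simulator emulates the benchmark design: patients accrue uniformly
over two years (2200 for shape γ = 0.5), partition membership is
multinomial over quartile prevalences, arms are assigned 1:1 by fair
coin, and event times are Weibull with survival exp(−λt^γ), shared shape,
control scale λ_C = ln2/20^{2γ} (400-day median), and
λ_Ej = λ_C·e^{θⱼ}. *t₁* is the calendar day of the 300th death; every
death before *t₁* necessarily belongs to an already-enrolled patient, so
the 300th-smallest death time over the accrual stream is exactly the
interim day. Patients entering after *t₁* are re-drawn from the selected
partitions with renormalised prevalences — enrichment at a maintained
accrual rate, without which a 300-death stage-2 target can be unreachable
when a single quartile continues. *t₂* is the day of the 300th stage-2
death; stage-2 entrants later than *t₂* contribute nothing. The
follow-up extension is 250 days for γ = 0.5 (110 and 77 days for γ = 1
and 1.5, keeping total event counts comparable).

Each replicate runs the full pipeline twice (δ > 0 and δ = 0) and
aggregation conditions on the realised selected set: selection
probabilities (summing to one over outcomes including the stop),
per-partition bias and RMSE of both estimators under both follow-up
conventions, simultaneous coverage of the naive and duality regions, and
the tail error (probability that at least one upper bound falls below the
truth). Replicates are driven by independent spawned substreams of a
single seed, so results are bit-reproducible and order-independent;
replicates that stop contribute to selection probabilities only, and
degenerate replicates (no interim information in a partition, stage-2
target unreachable) are counted and excluded.

What the simulator does not emulate: non-proportional hazards within a
partition, prognostic-only biomarker effects (the estimators' behaviour
is unchanged, as only hazard ratios enter), non-administrative dropout,
staggered or non-uniform accrual, and ties in event times (Weibull draws
are almost surely tie-free; the log-rank variance nevertheless carries
the standard hypergeometric tie factor for real data, where a censoring
sharing a day with an event is treated as occurring after it). Passing
simulation checks therefore supports the estimators under clean
proportional-hazards conditions, not under informative censoring or
model misspecification.

## Problem sizes and reproduction

The acceptance script evaluates the deterministic worked-example
quantities directly from the printed summary statistics and recomputes
the stochastic quantities at desk scale, chosen so Monte-Carlo error is
small relative to each target: 20,000 stage-1-only replicates for
selection probabilities, 5,000 full two-stage replicates (with duality
intervals) for the conditional-bias and conditional-coverage targets,
and 2,000 full replicates per remaining configuration for the coverage
floor. Conditional bias is reported as the signed mean of
θ̂_N − θ; with everything selected, the conditioning event (weighted
interim mean ≤ 0) drags the estimate toward benefit, so the signed bias
is negative with the magnitude reported in the benchmark tables. The
test suite mirrors these checks at the same sizes with fixed seeds,
alongside the module-level oracles (quadrature, subset enumeration,
grid-search inversion, independent log-rank implementation).
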