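# enrichsurv

Point and interval estimation after biomarker-driven subpopulation
selection in two-stage adaptive enrichment trials with time-to-event
outcomes.

## The problem

In a two-stage enrichment trial the full population is partitioned into
*K* disjoint biomarker strata with prevalences *p₁,…,p_K*. Stage 1
recruits from everywhere; at an interim analysis (calendar time *t₁*,
typically the day a prespecified number of events has occurred) the
per-partition log hazard ratios are estimated and a prespecified rule
selects the subset 𝒮 ⊆ {1,…,K} of partitions that continue — stage-2
recruitment is restricted to 𝒮 (or the trial stops for futility).
Because the same interim data drive both the selection and the final
analysis, the naive end-of-trial estimates in the selected partitions are
biased and their confidence intervals undercover, exactly where the
numbers matter most: in a confirmatory readout.

`enrichsurv` implements, for survival endpoints analysed by log-rank
score statistics:

- **Score summaries with independent increments.** For partition *j*,
  the score statistic and Fisher information give
  θ̂₁ⱼ = S₁ⱼ/V₁ⱼ ~ N(θⱼ, 1/V₁ⱼ) at the interim; the post-interim
  increment θ̂₂ⱼ = (S_Nⱼ − S₁ⱼ)/(V_Nⱼ − V₁ⱼ) is asymptotically
  independent of the interim score, and the naive estimator is their
  inverse-variance combination
  θ̂_Nⱼ = (σ₂ⱼ²θ̂₁ⱼ + σ₁ⱼ²θ̂₂ⱼ)/(σ₁ⱼ² + σ₂ⱼ²). Stage-1 patients
  without events at *t₁* may be followed to a prespecified *t̃₁ > t₁*.
- **Selection rules with truncation bounds.** A prefix ("adaptive
  threshold") rule for ordered partitions — continue with the largest
  *s* such that Σⱼ≤ₛ pⱼθ̂₁ⱼ / Σⱼ≤ₛ pⱼ ≤ b — and an independent rule
  (continue with every partition with θ̂₁ⱼ ≤ b). Each selected
  partition gets the interval (lⱼ, wⱼ) of interim estimates compatible
  with the observed selection.
- **A conditionally unbiased point estimator (UMVCUE).** The
  Rao-Blackwell conditional expectation of the unbiased increment given
  the complete sufficient statistic and the selection event,

  θ̂_Uⱼ = θ̂_Nⱼ − σ₂ⱼ²/√(σ₁ⱼ²+σ₂ⱼ²) ·
  [φ(g(lⱼ)) − φ(g(wⱼ))] / [Φ(g(lⱼ)) − Φ(g(wⱼ))],
  g(x) = √(σ₁ⱼ²+σ₂ⱼ²)/σ₁ⱼ² · (θ̂_Nⱼ − x).

- **Confidence intervals.** Naive intervals θ̂_Nⱼ ± z_{α/(2|𝒮|)}σ_Nⱼ,
  and simultaneous *duality* intervals obtained by inverting a closed
  test whose intersection hypotheses use Šidak-adjusted stagewise
  p-values combined with the weighted inverse-normal function
  C(p₁,p₂) = 1 − Φ(ω₁Φ⁻¹(1−p₁) + ω₂Φ⁻¹(1−p₂)).
- **A Weibull trial simulator** that generates complete two-stage trials
  (uniform accrual, multinomial partition membership, enrichment of the
  stage-2 accrual stream) and aggregates selection probabilities,
  conditional bias/RMSE and simultaneous coverage.

## Worked example

A two-partition trial (prevalences 0.2/0.8, futility threshold b = 0)
summarised by its printed statistics — interim estimates (−0.902, −0.419),
combined estimates (−0.746, −0.362) and increments (−0.609, −0.301), each
with variances:

```
python examples/worked_example.py
```

```
--- rule: adaptive_threshold ---
selected partitions: [1, 2]
partition 1: theta1=-0.902  naive=-0.746  UMVCUE=-0.746  bounds=(-inf, +1.676)  naive CI=(-1.415, -0.077)
partition 2: theta1=-0.419  naive=-0.362  UMVCUE=-0.359  bounds=(-inf, +0.226)  naive CI=(-0.878, +0.154)

--- rule: independent ---
selected partitions: [1, 2]
partition 1: theta1=-0.902  naive=-0.746  UMVCUE=-0.739  bounds=(-inf, +0.000)  naive CI=(-1.415, -0.077)
partition 2: theta1=-0.419  naive=-0.362  UMVCUE=-0.335  bounds=(-inf, +0.000)  naive CI=(-0.878, +0.154)
```

Both rules select both partitions. The truncation bounds under the prefix
rule are w₁ = 1.676 and w₂ = 0.226; under the independent rule both are
b = 0. The bias-adjusted estimates move toward zero — selection through an
upper bound makes the naive log-hazard-ratio estimates too favourable —
and the correction is larger the tighter the bound. The naive intervals
split α = 0.05 across the two selected partitions (z = 2.241).

The other examples run a single simulated trial end to end
(`examples/simulate_one_trial.py`) and a small Monte-Carlo bias/coverage
study (`examples/operating_characteristics.py`).

A thin command-line interface wraps the same pipeline:

```
enrichsurv estimate --summaries summ.json --design design.yaml --out report.json
enrichsurv simulate --scenario scenario.yaml --reps 1000 --seed 1 --out oc.csv
enrichsurv fixture  --out subjects.csv --seed 3 --design-out design.yaml
```

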