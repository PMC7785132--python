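"""Estimation from published per-partition summary statistics.

A two-partition enrichment trial (high-risk vs low/intermediate-risk
leukaemia patients, futility threshold b = 0) summarised by its interim
estimates, combined estimates and post-interim increments.  We run the
full pipeline under both selection rules and print the bias-adjusted
estimates next to the naive ones.
"""

import math

from enrichsurv import (PartitionSummaries, ScoreSummary, TrialDesign,
                        estimate_from_summaries)

summaries = PartitionSummaries(
    K=2,
    stage1=[ScoreSummary.from_estimate(-0.902, 0.191),
            ScoreSummary.from_estimate(-0.419, 0.103)],
    combined=[ScoreSummary.from_estimate(-0.746, 0.089),
              ScoreSummary.from_estimate(-0.362, 0.053)],
    increment=[ScoreSummary.from_estimate(-0.609, 0.167),
               ScoreSummary.from_estimate(-0.301, 0.108)],
)

for rule in ("adaptive_threshold", "independent"):
    design = TrialDesign(K=2, prevalences=(0.2, 0.8), futility_threshold=0.0,
                         rule=rule, alpha=0.05,
                         weights=(math.sqrt(0.75), math.sqrt(0.25)))
    report = estimate_from_summaries(summaries, design)
    print(f"--- rule: {rule} ---")
    print(f"selected partitions: {list(report.selection.selected)}")
    for j, e in sorted(report.estimates.items()):
        l, w = e.bounds
        print(f"partition {j}: theta1={e.theta1:+.3f}  "
              f"naive={e.thetaN:+.3f}  UMVCUE={e.umvcue:+.3f}  "
              f"bounds=({l:+.3f}, {w:+.3f})  "
              f"naive CI=({e.naive_ci[0]:+.3f}, {e.naive_ci[1]:+.3f})")
    print()

print("The bias-adjusted (UMVCUE) estimates sit closer to zero than the")
print("naive ones: selection through an upper truncation bound makes the")
print("naive log-hazard-ratio estimates too favourable, and the correction")
print("is larger under the independent rule (tighter bound w = 0).")
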