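"""Simulate a single two-stage enrichment trial end to end.

Draws one Weibull trial (four quartile partitions, interim at 300 deaths,
stage-2 enrichment to the selected partitions), runs the whole pipeline on
the subject records and prints the per-partition report.
"""

import numpy as np

from enrichsurv.simulator import benchmark_scenario, simulate_trial

scenario = benchmark_scenario(config=3)  # effects (-0.41, -0.22, -0.10, 0)
rng = np.random.default_rng(7)
records, times, selection, report = simulate_trial(scenario, rng)

print(f"subjects: {len(records)}")
if report.stopped:
    print("trial stopped at the interim (futility)")
else:
    print(f"analysis days: t1={times.t1:.0f}  t~1={times.t_tilde1:.0f}  "
          f"t2={times.t2:.0f}")
    print(f"selected partitions: {list(selection.selected)}")
    for j, e in sorted(report.estimates.items()):
        d = e.duality
        dual = (f"({d.lower:+.3f}{'' if d.lower_informative else '*'}, "
                f"{d.upper:+.3f}{'' if d.upper_informative else '*'})")
        print(f"partition {j}: true={scenario.theta[j - 1]:+.3f}  "
              f"naive={e.thetaN:+.3f}  UMVCUE={e.umvcue:+.3f}  "
              f"naive CI=({e.naive_ci[0]:+.3f}, {e.naive_ci[1]:+.3f})  "
              f"duality CI={dual}")
    print("* = bound fixed at 0 by the testing procedure (non-informative)")
    print()
    print("Negative log hazard ratios favour the experimental arm; the")
    print("duality intervals invert the closed combination test and stay")
    print("valid simultaneously across the selected partitions.")
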