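"""Small Monte-Carlo study of selection bias and its correction.

Runs a reduced replicate count of the near-null benchmark configuration
(all log hazard ratios 0.0198, i.e. the experimental arm is slightly
harmful everywhere and stopping is the ideal decision) and prints the
selection probabilities plus, conditional on selecting all partitions, the
bias of the naive and the conditionally unbiased estimator.
"""

from enrichsurv.simulator import benchmark_scenario, operating_characteristics

scenario = benchmark_scenario(config=1)
oc = operating_characteristics(scenario, n_reps=1000, seed=42,
                               full=True, intervals=True)

print("selection probabilities:")
for sel, p in sorted(oc.selection_probabilities.items()):
    label = "stop" if not sel else str(list(sel))
    print(f"  {label:>14}: {p:.3f}")

all4 = (1, 2, 3, 4)
print("\nconditional on all four partitions selected (partition 1):")
for est in ("naive", "umvcue"):
    for variant, label in (("frozen", "stage 1 frozen at t1"),
                           ("tilde", "stage 1 followed to t~1")):
        print(f"  {est:>6}, {label}: bias {oc.bias(all4, 1, est, variant):+.4f}"
              f"  rmse {oc.rmse(all4, 1, est, variant):.4f}")

print(f"\nduality simultaneous coverage (all selected): "
      f"{100 * oc.coverage(all4, 'duality'):.1f}%")
print(f"naive   simultaneous coverage (all selected): "
      f"{100 * oc.coverage(all4, 'naive'):.1f}%")
print()
print("Selecting every partition requires the weighted interim estimate to")
print("look favourable, so the naive estimator is biased towards benefit;")
print("the Rao-Blackwell correction removes nearly all of that bias, and")
print("the duality regions hold their nominal 95% simultaneous coverage.")
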