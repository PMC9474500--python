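"""Detect non-equilibrium steady-state flow in a driven three-state system.

The driven three-state preset violates detailed balance with a cycle
rate-product ratio of 10, i.e. delta_G = -ln(10) ~ -2.30 k_BT of free
energy dissipated per counter-clockwise cycle. This script simulates a
reduced dataset, infers the model, and shows that the sign (and rough
magnitude) of the cycle free energy is recovered — while each individual
rate constant carries a larger relative error.
"""

import fretbench as fb

model, config = fb.presets.driven_three_state(seed=3)
config.n_traces = 40  # reduced for a quick demonstration
dataset = fb.simulate_dataset(model, config)

print(f"detailed balanced? {fb.is_detailed_balanced(model)}")
gt_flow = fb.cycle_flow_free_energy(model, (0, 1, 2))
print(f"ground-truth delta_G = {gt_flow.delta_g:.3f} k_BT")

fit = fb.fit_ensemble_hmm(dataset.traces, n_states=3, seed=0)
inferred = fit.to_kinetic_model()
flow = fb.cycle_flow_free_energy(inferred, (0, 1, 2))
dev = fb.percent_deviation(inferred, model)

print(f"inferred delta_G     = {flow.delta_g:.3f} k_BT "
      f"(negative = counter-clockwise flow)")
print(f"max rate deviation:  {dev.max_rate_deviation:.1f}%")
print(f"mean rate deviation: {dev.mean_rate_deviation:.1f}%")
print("systematic rate errors partially cancel in the cycle ratio, so the")
print("flow direction is more robust than any single rate constant")
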