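"""Resolve kinetic heterogeneity with tied-emission hidden states.

The heterogeneous preset has four hidden states but only two visible
FRET efficiencies (0.25 and 0.75): each FRET level hides a fast- and a
slow-exchanging state, so the dwell-time distribution of each level is
bi-exponential. A plain 2-state HMM cannot reproduce that; a 4-state
HMM whose emission parameters are tied in pairs can. The script compares
both fits through cumulative dwell-time distributions simulated from
each inferred model at heavy oversampling — the sup-norm distance to the
ground-truth distribution is the figure of merit.
"""

import numpy as np

import fretbench as fb

model, config = fb.presets.heterogeneous_four_state(seed=3)
config.n_traces = 120  # reduced for a quick demonstration
dataset = fb.simulate_dataset(model, config)

fit2 = fb.fit_ensemble_hmm(dataset.traces, n_states=2, seed=0)
fit4 = fb.fit_ensemble_hmm(
    dataset.traces, n_states=4, seed=0, tie_groups=[[0, 1], [2, 3]]
)

rng = np.random.default_rng(0)
kw = dict(oversample_factor=50, reference_points=10_000, sampling_rate=5.0)
cdf_gt = fb.cumulative_dwell_cdf(model, rng=rng, **kw)
cdf2 = fb.cumulative_dwell_cdf(fit2.to_kinetic_model(), rng=rng, **kw)
cdf4 = fb.cumulative_dwell_cdf(fit4.to_kinetic_model(), rng=rng, **kw)

print(f"2-state fit FRET means: {fit2.fret_means.round(3)}")
print(f"tied 4-state FRET means: {fit4.fret_means.round(3)}")
for cls, label in ((0, "low-FRET"), (1, "high-FRET")):
    d2 = cdf_gt.sup_distance(cdf2, cls)
    d4 = cdf_gt.sup_distance(cdf4, cls)
    print(f"{label} dwell-CDF distance to GT: 2-state {d2:.3f}, tied 4-state {d4:.3f}")
print("the tied model reproduces the bi-exponential dwell distribution;")
print("the 2-state model cannot, whatever its two rate constants")
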