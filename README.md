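# fretbench

Simulate, infer and benchmark kinetic models from single-molecule FRET
trajectories.

Single-molecule FRET (smFRET) time traces report conformational
dynamics of individual biomolecules: a molecule hops between states
with distinct FRET efficiencies, and the dwell times encode the
transition rate constants `k_ij` (s⁻¹). Many analysis tools exist for
turning traces into kinetic models, and their accuracy can only be
judged against data with known ground truth. `fretbench` closes that
loop in one package, for tool developers and experimentalists who want
to validate an analysis pipeline:

* **simulate** — realistic camera-style (TIRF) trace generation from a
  continuous-time Markov model: photobleach-limited trace lengths,
  within-frame state averaging (camera blur), state-specific Gaussian
  channel noise, per-molecule intensity variation and dye blinking —
  with the ground truth retained;
* **infer** — a reference ensemble Gaussian-emission hidden Markov
  model: joint Baum–Welch across traces, Viterbi idealisation,
  censoring-aware dwell-time compilation, exponential maximum
  likelihood (`k = 1/mean dwell`), rate conversion by matrix logarithm
  `K = logm(P)/Δt`, BIC model selection, parametric-bootstrap
  confidence intervals, and a tied-emission mode for kinetic
  heterogeneity (states sharing a FRET efficiency but not kinetics);
* **evaluate** — benchmark statistics: percent deviation from ground
  truth, the finite-data lower bound on rate uncertainty
  (`SD(k̂) = k·n/((n−1)√(n−2))` for `n` observed dwells, verified by
  Monte Carlo), cumulative dwell-time distributions simulated at
  ~200× oversampling, histogram SNR `|μ₁−μ₂|/√(σ₁²+σ₂²)`,
  equilibrium constants `K = k21/k12`, and non-equilibrium cycle free
  energy `ΔG = −ln[(k21·k32·k13)/(k12·k23·k31)]` in k_BT units.

## Worked example

```python
import fretbench as fb

model, config = fb.presets.two_state_archetype(seed=1)   # k12=0.10, k21=0.20 s^-1
dataset = fb.simulate_dataset(model, config)             # 75 traces, 5 Hz
fit = fb.fit_ensemble_hmm(dataset.traces, n_states=2, seed=0)
dev = fb.percent_deviation(fit.to_kinetic_model(), model)
print(fit.rates, dev.max_rate_deviation, dev.max_fret_deviation)
```

Running `python examples/infer_rates_from_traces.py` (a 30-trace
variant with bootstrap intervals) prints:

```
converged after 7 EM iterations (method: matrix_log)
k12: inferred 0.0962 s^-1 (GT 0.10, 95% CI [0.0845, 0.1020])
k21: inferred 0.1907 s^-1 (GT 0.20, 95% CI [0.1659, 0.2115])
FRET means: [0.299 0.699] (GT [0.3 0.7])
max rate deviation:  4.6%
max FRET deviation:  0.3%
```

The inferred rates sit a few percent below the ground truth (camera
blur hides the fastest events), well inside the published cross-tool
accuracy envelope for this dataset class (≤ 12% for rates, ≤ 17% for
FRET efficiencies), and the bootstrap intervals bracket the truth.
Other scripts under `examples/` demonstrate dataset simulation,
steady-state-flow detection in a driven three-state system, the
finite-data uncertainty bound, and resolving kinetic heterogeneity
with tied-emission states.

A thin CLI wraps the same library, including the full consistency loop
(simulate a model, re-infer it, score the result):

```sh
fretbench benchmark --model model.cfg --out run/ --seed 7
```

See `docs/methods.md` for the model, the noise processes, all default
parameters and the design decisions behind them.

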