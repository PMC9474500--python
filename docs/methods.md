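# Methods

`fretbench` closes the simulate → infer → evaluate loop for kinetic
analysis of single-molecule FRET (smFRET) trajectories: it generates
realistic camera-style intensity traces from a known continuous-time
kinetic model, infers the model back with a reference ensemble hidden
Markov model, and scores the result with statistics designed for
benchmarking kinetic-inference tools.

## Kinetic model

A molecule switches between `n` conformational states with
first-order rate constants `k_ij` (s⁻¹); each state has a FRET
efficiency `E_i ∈ [0, 1]`. The generator `Q` (off-diagonal `k_ij`,
diagonal `−Σ_j k_ij`) defines a continuous-time Markov chain whose
stationary distribution π solves `πQ = 0` (computed as the null space
of `Qᵀ`, residual tolerance 1e−10). The canonical state order is
ascending FRET efficiency, ties broken by larger total exit rate;
every model is permuted into this order on validation so that
ground-truth/inferred comparisons are well defined even for permuted
submissions or degenerate efficiencies.

For three or more states the chain need not obey detailed balance. The
free-energy drop per traversal of a cycle, in units of k_BT, is

    ΔG(1→2→3→1) = −ln[(k21·k32·k13) / (k12·k23·k31)]

Negative ΔG flags net counter-clockwise flux (a non-equilibrium steady
state sustained by external energy input). No temperature parameter is
carried: only the dimensionless ratio ever enters. Detailed balance is
checked by the Kolmogorov criterion — zero ΔG on every cycle of a
cycle basis of the connectivity graph, with any one-way edge failing
immediately.

## Trace simulation

Per molecule:

1. **Trace length** — exponential with the photobleaching rate;
   draws below `min_length` are rejected and redrawn, draws above
   `max_length` are truncated. This reproduces the practice of
   discarding very short traces and stopping acquisition at a fixed
   movie length.
2. **State path** — the initial state is drawn from π; from each
   state, candidate dwell times to every reachable state are drawn
   from the corresponding exponential distributions and the shortest
   draw wins (equivalent to Gillespie sampling). The path is continuous
   in time, so transitions can fall inside camera frames.
3. **Discretisation** — frames are half-open intervals `[t, t+Δt)` at
   the sampling rate; each frame records the fraction of the frame
   period spent in each state (occupancy). Frame count is
   `floor(duration·rate)`.
4. **Emission** — one multichannel Gaussian draw per state visited in
   a frame (donor, FRET-sensitised acceptor, directly excited
   acceptor; per-state mean vector and covariance), combined as the
   occupancy-weighted average. Drawing noise per visited state and
   then averaging (rather than drawing once from the averaged mean)
   slightly reduces the variance of mixed frames, mimicking
   integration of independent photon streams within the bin.
5. **Per-molecule variation** (optional) — per-trace state means are
   redrawn from `N(μ_I, 5·√μ_I)` (negative draws resampled so means
   stay Gaussian-shaped without a point mass at zero), and a common
   brightness factor `1.20^r`, `r ~ U[−1, 1]`, multiplies all
   channels, confining it to `[0.83, 1.20]`. The common factor cancels
   in the FRET ratio; the mean jitter does not, and broadens the FRET
   histogram between molecules.
6. **Blinking** (optional) — each dye is an independent two-state
   bright/dark process (defaults 0.01 s⁻¹ to dark, 0.1 s⁻¹ to
   bright). During acceptor-dark stretches no transfer occurs: the
   sensitised signal returns to the donor channel and the apparent
   FRET efficiency drops to zero; the directly excited acceptor
   channel goes dark as well, which is what experimental
   alternating-excitation schemes exploit to recognise these events.
   During donor-dark stretches both donor-excited channels are dark
   and the FRET ratio is undefined.

FRET efficiency is the uncorrected proximity ratio `E = A/(D+A)`,
undefined (NaN) when `D+A ≤ 0`. Randomness is fully reproducible:
per-trace substreams derive from `(seed, trace index)`, so a dataset
is byte-identical across runs and single traces can be regenerated.

What the generator does **not** emulate: photon-by-photon statistics
(shot noise enters only through the Gaussian channel widths), spectral
crosstalk and γ-correction, diffusing-molecule confocal bursts, and
drift/baseline wander. Passing tests therefore demonstrate correctness
of the kinetic inference chain under Gaussian camera noise, not
robustness to every experimental artefact.

## Reference conditions

Three preset archetypes fix the study conditions (emission means total
1600 counts/frame; channel SDs chosen so the per-state FRET SD is
≈ 0.0707, i.e. adjacent states 0.4 apart score SNR ≈ 4 on the
histogram):

| preset | states | rates (s⁻¹) | traces | rate (Hz) | ~frames | extras |
|---|---|---|---|---|---|---|
| `two_state_archetype` | E = 0.3/0.7 | k12 = 0.10, k21 = 0.20 | 75 | 5 | 59.5k | none |
| `driven_three_state` | E = 0.2/0.5/0.8 | cycle ratio 10 ⇒ ΔG = −ln 10 | 150 | 10 | 82.6k | mean jitter + brightness |
| `heterogeneous_four_state` | E = 0.25/0.25/0.75/0.75 | pair exchange 0.5 vs 0.05, cross 0.02 | 250 | 5 | 56.8k | + blinking |

These sizes match the published reference datasets for this kind of
benchmark; the rate constants are the package's own choices consistent
with the printed dataset statistics (e.g. 75 traces × mean 160 s at
5 Hz ≈ 59,500 frames; stationary occupancy 2/3 gives ≈ 793 dwells per
transition).

## Inference

A single 1-D Gaussian-emission HMM over the FRET efficiency is fit
jointly to all traces (Baum–Welch; per-trace forward–backward
statistics accumulated into one shared parameter set). The 1-D
emission model is the common denominator of published tools; a 2-D
donor/acceptor variant is left as an extension hook.

* **Masking.** Frames with undefined FRET are excluded from the
  likelihood. In addition, dye-dark frames are masked by the standard
  alternating-excitation check: acceptor-direct signal (or total
  intensity) below 30% of the per-trace median. Without this filter,
  the exact-zero FRET population produced by acceptor blinking is
  absorbed by a spurious zero-variance state.
* **Initialisation.** k-means cluster means on the pooled FRET values;
  per-cluster SDs; transition matrix 0.95 on the diagonal; initial
  probabilities from cluster frequencies. Restarts (default 5) jitter
  the means by ±0.02; the best final log-likelihood wins. Convergence:
  relative log-likelihood change < 1e−6, max 1000 iterations. EM
  monotonicity is asserted in the test suite on every fit.
* **Tied emissions (kinetic heterogeneity).** Hidden states may be
  grouped to share one emission mean/SD, re-estimated from pooled
  sufficient statistics each M-step. The initial point is projected
  into the tied family (otherwise the first constrained M-step could
  lower the likelihood), and the within-group symmetry is broken by
  asymmetric initial self-transition probabilities (0.99 vs 0.90),
  bracketing a slow and a fast hidden state. Group structure is
  user-specified, not searched.
* **Rates.** The per-frame transition matrix is converted to rate
  constants by the principal matrix logarithm `K = logm(P)/Δt`, which
  correctly attributes multiple transitions within one frame; negative
  off-diagonals (numerical artefacts) are clipped. When the principal
  log is complex the element-wise fallback `k_ij = P_ij/Δt` is used,
  and the fallback is reported alongside whenever the two differ by
  more than 5% on any rate.
* **Dwells.** Viterbi paths (per trace) are compiled into dwell
  records; the first and last run of each trace, and runs bordering
  masked stretches, are censored and excluded from the exponential
  MLE `k = 1/mean(dwell)`. The censoring convention avoids the
  downward bias of boundary-truncated dwells; binned/censored-likelihood
  variants are deliberately out of scope.
* **Model selection.** BIC (`−2 lnL + p ln N`, with `p` = emission
  means + SDs (per tied group if tied) + `n(n−1)` transition +
  `n−1` initial probabilities) over 1..max states. Candidates
  containing a state pair with pairwise separation
  `|μ_i−μ_j|/√(σ_i²+σ_j²) < 1` are excluded as unresolvable: with a
  1-D Gaussian emission model, such extra states almost always absorb
  camera-blurred transition frames (an equal-weight Gaussian pair only
  becomes bimodal above separation √2, so 1 is conservative). States
  sharing a FRET efficiency but differing kinetically are reachable
  only through explicit tied-emission fits — with emissions as the
  only evidence they are not identifiable from the histogram.
* **Uncertainty.** Parametric bootstrap: re-simulate datasets from the
  inferred model at matched trace count and lengths (continuous-time
  paths at the inferred rates, occupancy-weighted Gaussian FRET
  emissions — exactly the generative model the HMM assumes), refit,
  and report percentile intervals (default 95%). Refit failures are
  dropped with a reported count.

## Benchmark statistics

* **Finite-data lower bound.** For a transition observed `n` times, a
  replicate experiment draws `n` exponential dwells and estimates
  `k̂ = 1/mean`; the SD of `k̂` across replicates (default 1e5; the
  1e6 used in large studies is available by argument, MC error
  shrinking as 1/√reps) is the tightest uncertainty any tool could
  honestly report. It matches the closed form
  `SD = k·n/((n−1)√(n−2))` (the MLE is inverse-Gamma distributed).
  At the two-state reference statistics (793 dwells) this is ≈ 3.6% of
  the rate — reported confidence intervals narrower than this are
  flagged as implausible in the benchmark report.
* **Cumulative dwell-time CDFs.** Models that share visible FRET
  states but differ in hidden structure are discriminated by
  simulating continuous-time trajectories totalling ~200× the
  reference dataset length, grouping hidden states into FRET classes
  (single-linkage chaining, tolerance 0.05 — degenerate designs are
  exactly equal, the tolerance covers inference jitter), and
  accumulating class residence times (re-entries within a class do not
  split a dwell; boundary dwells are dropped). CDFs are evaluated on
  200 log-spaced points from a tenth of the frame period to 10× the
  slowest expected dwell, resolving multi-exponential tails.
* **SNR.** From a two-component Gaussian-mixture fit of the pooled
  FRET histogram: `SNR = |μ₁−μ₂|/√(σ₁²+σ₂²)`. If one component
  explains the histogram at least as well by BIC, the populations are
  unresolvable and SNR is reported as 0.
* **Deviation / CV.** Percent deviation `100·|k_inf−k_gt|/k_gt` per
  rate (and per FRET efficiency) after canonical ordering, with max
  and mean summaries; coefficient of variation uses the sample SD
  (n−1 denominator). State-count mismatches produce a structured
  mismatch report, never a silent comparison.

## Problem sizes used in the test suite

The acceptance-grade checks run the full two-state reference dataset
(75 traces, ~59.5k frames) and 1e5 lower-bound replicates. The
flow-sign experiment (100 independent simulate+infer rounds of the
driven three-state model) uses 24 traces of mean length ~30 s per
round — sign recovery at this driving strength (cycle ratio 10) is
insensitive to dataset size, and the reduced size keeps the suite
desk-scale. Unit tests use further reduced datasets (~12k frames).

## Known limitations

* Camera blur is simulated but not modelled in the likelihood; rates a
  few percent below truth at rate/sampling ratios ≳ 0.05 are expected,
  mirroring the systematic underestimation seen across published
  tools.
* The 1-D emission model cannot exploit donor/acceptor covariance.
* Bootstrap intervals inherit any bias of the point estimate; they
  quantify spread, not accuracy.
* The dwell-CDF simulator loops over state transitions in Python;
  oversampling factors ≫ 1000 on fast models get slow.
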