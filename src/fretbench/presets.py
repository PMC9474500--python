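"""Reference benchmark conditions: models and simulation configurations.

Three dataset archetypes cover the canonical difficulty ladder of
kinetic smFRET analysis:

* a clean two-state equilibrium system (75 traces, 5 Hz, ~59,500
  frames, SNR ~4) — the baseline every tool should nail;
* a driven three-state system violating detailed balance (150 traces,
  10 Hz, ~82,600 frames, SNR ~3, per-molecule intensity variation) —
  probes recovery of non-equilibrium cycle flux;
* a four-hidden-state system with pairwise-degenerate FRET efficiencies
  (250 traces, 5 Hz, ~56,800 frames, intensity variation and dye
  blinking) — probes kinetic heterogeneity, where dwell-time
  distributions are multi-exponential although only two FRET states are
  visible.

Emission means are in arbitrary camera counts; the channel noise SDs
are chosen so that the per-state FRET-efficiency SD is ~0.0707, which
puts adjacent states 0.4 apart at SNR 4 (or 0.3 apart at ~SNR 3).
"""

from __future__ import annotations

import numpy as np

from .models import KineticModel, validate_model
from .simulate import SimulationConfig

#: published size of the two-state reference dataset (frames)
TWO_STATE_REFERENCE_POINTS = 59_486
#: published size of the driven three-state reference dataset (frames)
THREE_STATE_REFERENCE_POINTS = 82_594
#: published size of the heterogeneous four-state reference dataset (frames)
HETEROGENEOUS_REFERENCE_POINTS = 56_794

_TOTAL_COUNTS = 1600.0  # donor + acceptor mean counts per frame
_DIRECT_COUNTS = 1200.0  # acceptor counts under direct excitation


def _emissions(fret_values, fret_sd=0.0707):
    """Channel means/covariances giving a target per-state FRET SD.

    With equal independent noise sigma on donor and acceptor, error
    propagation on E = A/(A+D) gives
    SD(E) ~= sigma * sqrt(A^2 + D^2) / T^2, solved here for sigma.
    """
    means, covs = [], []
    for e in fret_values:
        a = e * _TOTAL_COUNTS
        d = (1.0 - e) * _TOTAL_COUNTS
        sigma = fret_sd * _TOTAL_COUNTS**2 / np.hypot(a, d)
        means.append([d, a, _DIRECT_COUNTS])
        covs.append(np.diag([sigma**2, sigma**2, (0.075 * _DIRECT_COUNTS) ** 2]))
    return np.array(means), np.array(covs)


def two_state_archetype(seed: int = 0) -> tuple[KineticModel, SimulationConfig]:
    """Clean two-state equilibrium benchmark.

    k12 = 0.10 s^-1, k21 = 0.20 s^-1 (so K = 2 and the stationary
    occupancy of the low-FRET state is 2/3), FRET efficiencies 0.3/0.7,
    75 traces at 5 Hz with photobleach-limited lengths (mean ~160 s,
    bounds 30-300 s) totalling ~59,500 frames.  No intensity variation
    or blinking: SNR ~4 from channel noise alone.
    """
    model = validate_model(
        KineticModel(rates=np.array([[0.0, 0.10], [0.20, 0.0]]), fret=np.array([0.3, 0.7]))
    )
    means, covs = _emissions(model.fret)
    config = SimulationConfig(
        sampling_rate=5.0,
        bleach_rate=1.0 / 160.0,
        min_length=30.0,
        max_length=300.0,
        n_traces=75,
        emission_means=means,
        emission_cov=covs,
        enable_mean_jitter=False,
        enable_brightness=False,
        enable_blinking=False,
        seed=seed,
    )
    return model, config


def driven_three_state(seed: int = 0) -> tuple[KineticModel, SimulationConfig]:
    """Non-equilibrium three-state benchmark with counter-clockwise flow.

    The reverse cycle product exceeds the forward one tenfold, giving
    delta_g = -ln(10) ~= -2.30 k_BT for the cycle (1, 2, 3).  150
    traces at 10 Hz (mean length ~55 s) totalling ~82,600 frames, with
    per-molecule state-mean jitter and brightness variation enabled.
    """
    rates = np.array(
        [
            [0.0, 0.10, 0.20],
            [0.25, 0.0, 0.15],
            [0.10, 0.30, 0.0],
        ]
    )
    model = validate_model(KineticModel(rates=rates, fret=np.array([0.2, 0.5, 0.8])))
    means, covs = _emissions(model.fret)
    config = SimulationConfig(
        sampling_rate=10.0,
        bleach_rate=1.0 / 46.0,
        min_length=10.0,
        max_length=200.0,
        n_traces=150,
        emission_means=means,
        emission_cov=covs,
        enable_mean_jitter=True,
        enable_brightness=True,
        enable_blinking=False,
        seed=seed,
    )
    return model, config


def heterogeneous_four_state(seed: int = 0) -> tuple[KineticModel, SimulationConfig]:
    """Kinetic-heterogeneity benchmark: four hidden states, two FRET states.

    States 1/2 share E = 0.25 and states 3/4 share E = 0.75; one
    low/high pair exchanges fast (0.5 s^-1), the other slowly
    (0.05 s^-1), with slow cross-exchange (0.02 s^-1) inside each FRET
    class.  Class dwell-time distributions are therefore markedly
    bi-exponential.  250 traces at 5 Hz (~56,800 frames) with intensity
    variation and donor/acceptor blinking enabled.

    Canonical state order: (low fast, low slow, high fast, high slow).
    """
    # order: L-fast, L-slow, H-fast, H-slow
    rates = np.array(
        [
            [0.0, 0.02, 0.50, 0.0],
            [0.02, 0.0, 0.0, 0.05],
            [0.50, 0.0, 0.0, 0.02],
            [0.0, 0.05, 0.02, 0.0],
        ]
    )
    model = validate_model(
        KineticModel(rates=rates, fret=np.array([0.25, 0.25, 0.75, 0.75]))
    )
    means, covs = _emissions(model.fret)
    config = SimulationConfig(
        sampling_rate=5.0,
        bleach_rate=1.0 / 38.0,
        min_length=10.0,
        max_length=120.0,
        n_traces=250,
        emission_means=means,
        emission_cov=covs,
        enable_mean_jitter=True,
        enable_brightness=True,
        enable_blinking=True,
        blink_rates={"donor": (0.01, 0.1), "acceptor": (0.01, 0.1)},
        seed=seed,
    )
    return model, config
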