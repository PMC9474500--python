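"""Simulation of camera-based (TIRF-style) smFRET intensity trajectories.

The simulator mimics the data-generating process of a wide-field FRET
experiment: a continuous-time state trajectory per molecule (so that
transitions may fall inside a camera frame), a photobleach-limited trace
length, discretisation at the camera frame rate with time-weighted
averaging, state-specific multichannel Gaussian emissions, optional
per-molecule intensity variation (state-mean jitter and a global
brightness factor), and optional two-state dye blinking where an
acceptor dark period drives the apparent FRET efficiency to zero.

Ground truth (the generating model, state path and per-trace variation
factors) is retained alongside every dataset so inference results can be
benchmarked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import KineticModel, stationary_distribution, validate_model

CHANNELS = ("donor", "acceptor", "acceptor_direct")


@dataclass
class SimulationConfig:
    """All simulator knobs.

    Attributes
    ----------
    sampling_rate
        Camera frame rate in Hz; the frame period is ``1/sampling_rate``.
    bleach_rate
        Photobleaching rate in s^-1; trace lengths are exponential with
        this rate, redrawn below ``min_length`` and clipped at
        ``max_length``.
    emission_means
        Array (n_states, 3): mean counts per state for the donor,
        FRET-sensitised acceptor and directly excited acceptor channels.
    emission_cov
        Array (n_states, 3, 3): per-state channel covariance (counts^2).
    mean_jitter_scale
        Per-trace state means are drawn from N(mu_I, scale*sqrt(mu_I));
        the default scale of 5 reproduces typical molecule-to-molecule
        intensity spread.
    brightness_base
        Per-trace brightness factor base^r with r ~ U[-1, 1]; the default
        1.20 keeps factors in [0.83, 1.20].
    blink_rates
        ``{"donor": (to_dark, to_bright), "acceptor": (...)}`` in s^-1.
    """

    sampling_rate: float = 5.0
    bleach_rate: float = 1.0 / 160.0
    min_length: float = 30.0
    max_length: float = 300.0
    n_traces: int = 75
    emission_means: np.ndarray = None
    emission_cov: np.ndarray = None
    mean_jitter_scale: float = 5.0
    brightness_base: float = 1.20
    enable_mean_jitter: bool = False
    enable_brightness: bool = False
    enable_blinking: bool = False
    blink_rates: dict = field(
        default_factory=lambda: {"donor": (0.01, 0.1), "acceptor": (0.01, 0.1)}
    )
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.emission_means is not None:
            self.emission_means = np.asarray(self.emission_means, dtype=float)
            if np.any(self.emission_means < 0):
                raise ValueError("emission means must be non-negative")
        if self.emission_cov is not None:
            self.emission_cov = np.asarray(self.emission_cov, dtype=float)
            for c in self.emission_cov:
                if not np.allclose(c, c.T):
                    raise ValueError("emission covariance not symmetric")
                if np.linalg.eigvalsh(c).min() < -1e-9:
                    raise ValueError("emission covariance not positive semi-definite")

    @property
    def frame_period(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass(frozen=True)
class StatePath:
    """Continuous-time state trajectory: (state, entry time) segments."""

    states: np.ndarray  # segment state indices
    entry_times: np.ndarray  # strictly increasing, first at 0
    duration: float

    def __post_init__(self):
        t = np.asarray(self.entry_times, dtype=float)
        if len(t) == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0) or t[-1] >= self.duration:
            raise ValueError("entry times must start at 0, increase strictly, stay < duration")
        if np.any(np.asarray(self.states)[1:] == np.asarray(self.states)[:-1]):
            raise ValueError("consecutive segments must differ in state")


@dataclass
class Trace:
    """One molecule's discretised intensity trajectory."""

    times: np.ndarray  # frame start times, s
    donor: np.ndarray
    acceptor: np.ndarray
    acceptor_direct: np.ndarray
    fret: np.ndarray
    trace_id: str = ""
    sampling_rate: float = 0.0
    gt_occupancy: np.ndarray | None = None  # (n_frames, n_states) fractions

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A collection of traces plus the ground-truth sidecar (if simulated)."""

    traces: list
    sampling_rate: float
    gt_model: KineticModel | None = None
    gt_paths: list | None = None
    gt_factors: list | None = None  # per-trace (means, brightness) actually used
    seed: int | None = None

    @property
    def n_frames_total(self) -> int:
        return sum(t.n_frames for t in self.traces)

    def pooled_fret(self) -> np.ndarray:
        return np.concatenate([t.fret for t in self.traces]) if self.traces else np.array([])


def draw_trace_length(
    bleach_rate: float, min_length: float, max_length: float, rng: np.random.Generator
) -> float:
    """Photobleach-limited trace duration in seconds.

    Exponential(bleach_rate) with draws below ``min_length`` rejected
    (redrawn) and draws above ``max_length`` truncated to ``max_length``.
    """
    if min_length == max_length:
        return float(min_length)
    if bleach_rate <= 0:
        raise ValueError("bleach_rate must be > 0 unless min_length == max_length")
    for _ in range(1_000_000):
        t = rng.exponential(1.0 / bleach_rate)
        if t >= min_length:
            return float(min(t, max_length))
    raise RuntimeError("trace-length rejection sampling did not terminate")


def draw_initial_state(model: KineticModel, rng: np.random.Generator) -> int:
    """Initial state sampled from the stationary distribution."""
    return int(rng.choice(model.n_states, p=stationary_distribution(model)))


def simulate_state_path(
    model: KineticModel, duration: float, rng: np.random.Generator, initial_state: int | None = None
) -> StatePath:
    """Continuous-time trajectory by competing exponential dwell draws.

    From the current state, candidate dwell times to every reachable
    state are drawn from Exponential(k_ij); the shortest draw decides
    both the transition time and the destination.  The final segment is
    truncated at ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    state = draw_initial_state(model, rng) if initial_state is None else int(initial_state)
    states, entries = [state], [0.0]
    t = 0.0
    while True:
        k = model.rates[state]
        targets = np.flatnonzero(k > 0)
        if len(targets) == 0:  # single-state model
            break
        dwells = rng.exponential(1.0 / k[targets])
        j = int(np.argmin(dwells))
        t += dwells[j]
        if t >= duration:
            break
        state = int(targets[j])
        states.append(state)
        entries.append(t)
    return StatePath(np.array(states), np.array(entries), float(duration))


def _interval_frame_overlap(starts, ends, n_frames, period):
    """Fraction of each frame covered by the union of [start, end) intervals.

    Intervals must be disjoint and sorted.  Frames are half-open
    ``[f*period, (f+1)*period)``.
    """
    frac = np.zeros(n_frames)
    for s, e in zip(starts, ends):
        f0 = max(int(s / period), 0)
        f1 = min(int(np.ceil(e / period)), n_frames)
        if f1 <= f0:
            continue
        edges = np.arange(f0, f1 + 1) * period
        lo = np.maximum(edges[:-1], s)
        hi = np.minimum(edges[1:], e)
        frac[f0:f1] += np.clip(hi - lo, 0.0, None) / period
    return frac


def discretize_path(path: StatePath, sampling_rate: float) -> np.ndarray:
    """Per-frame state occupancy fractions, shape (n_frames, n_states').

    The number of frames is ``floor(duration * sampling_rate)``; each
    row gives the fraction of the frame period spent in each state and
    sums to 1.  Columns span ``max(state index) + 1`` states.
    """
    period = 1.0 / sampling_rate
    n_frames = int(np.floor(path.duration * sampling_rate))
    n_states = int(np.max(path.states)) + 1
    occ = np.zeros((n_frames, n_states))
    if n_frames == 0:
        return occ
    seg_ends = np.append(path.entry_times[1:], path.duration)
    for s in range(n_states):
        mask = path.states == s
        if mask.any():
            occ[:, s] = _interval_frame_overlap(
                path.entry_times[mask], seg_ends[mask], n_frames, period
            )
    return occ


def perturb_state_means(
    emission_means: np.ndarray, mean_jitter_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-trace state/channel means ~ N(mu_I, scale*sqrt(mu_I)), resampled if negative."""
    mu = np.asarray(emission_means, dtype=float)
    if mean_jitter_scale == 0:
        return mu.copy()
    sd = mean_jitter_scale * np.sqrt(mu)
    out = rng.normal(mu, sd)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mu[bad], sd[bad])
    raise RuntimeError("mean jitter resampling did not terminate")  # pragma: no cover


def draw_brightness_factor(brightness_base: float, rng: np.random.Generator) -> float:
    """Per-molecule brightness factor base^r with r ~ Uniform[-1, 1]."""
    if brightness_base <= 1:
        raise ValueError("brightness_base must exceed 1")
    return float(brightness_base ** rng.uniform(-1.0, 1.0))


def simulate_blinking(
    duration: float, to_dark: float, to_bright: float, rng: np.random.Generator
) -> np.ndarray:
    """Dark intervals of one dye as an array of (start, end) rows.

    The dye is a two-state (bright/dark) continuous-time process started
    bright; its long-run dark fraction is ``to_dark/(to_dark+to_bright)``.
    """
    if to_dark < 0 or to_bright < 0:
        raise ValueError("blink rates must be non-negative")
    dark_intervals = []
    t, bright = 0.0, True
    while t < duration:
        rate = to_dark if bright else to_bright
        if rate == 0:
            if not bright:
                dark_intervals.append((t, duration))
            break
        t_next = t + rng.exponential(1.0 / rate)
        if not bright:
            dark_intervals.append((t, min(t_next, duration)))
        t = t_next
        bright = not bright
    return np.array(dark_intervals).reshape(-1, 2)


def compute_fret(donor: np.ndarray, acceptor: np.ndarray) -> np.ndarray:
    """Proximity-ratio FRET efficiency E = A/(D+A); NaN where D+A <= 0."""
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, acceptor / total, np.nan)
    return e


def emit_trace(
    occupancies: np.ndarray,
    emission_means: np.ndarray,
    emission_cov: np.ndarray,
    rng: np.random.Generator,
    donor_dark: np.ndarray | None = None,
    acceptor_dark: np.ndarray | None = None,
    sampling_rate: float = 1.0,
    brightness: float = 1.0,
    trace_id: str = "",
) -> Trace:
    """Turn occupancy fractions into a noisy multichannel intensity trace.

    Per frame one Gaussian draw is made for every state visited in that
    frame and the draws are combined as the time-weighted (occupancy)
    average.  During acceptor-dark stretches no energy transfer occurs:
    the sensitised acceptor signal returns to the donor channel and the
    apparent FRET efficiency drops to zero.  During donor-dark stretches
    both donor and sensitised acceptor fall to zero (the directly excited
    acceptor channel is unaffected by donor blinking).
    """
    n_frames, n_states = occupancies.shape
    period = 1.0 / sampling_rate
    times = np.arange(n_frames) * period
    # one draw per (frame, state, channel); unused (zero-occupancy) draws are masked by weights
    draws = np.empty((n_frames, n_states, 3))
    for s in range(n_states):
        draws[:, s, :] = rng.multivariate_normal(emission_means[s], emission_cov[s], size=n_frames)
    donor = (occupancies * draws[:, :, 0]).sum(axis=1)
    acceptor = (occupancies * draws[:, :, 1]).sum(axis=1)
    acc_direct = (occupancies * draws[:, :, 2]).sum(axis=1)

    fa = 1.0 - (
        _interval_frame_overlap(acceptor_dark[:, 0], acceptor_dark[:, 1], n_frames, period)
        if acceptor_dark is not None and len(acceptor_dark)
        else 0.0
    )
    fd = 1.0 - (
        _interval_frame_overlap(donor_dark[:, 0], donor_dark[:, 1], n_frames, period)
        if donor_dark is not None and len(donor_dark)
        else 0.0
    )
    # acceptor dark: sensitised signal reroutes to the donor; donor dark: both channels off
    donor_out = fd * (donor + (1.0 - fa) * acceptor)
    acceptor_out = fd * fa * acceptor
    acc_direct_out = fa * acc_direct

    donor_out = brightness * donor_out
    acceptor_out = brightness * acceptor_out
    acc_direct_out = brightness * acc_direct_out
    return Trace(
        times=times,
        donor=donor_out,
        acceptor=acceptor_out,
        acceptor_direct=acc_direct_out,
        fret=compute_fret(donor_out, acceptor_out),
        trace_id=trace_id,
        sampling_rate=sampling_rate,
        gt_occupancy=occupancies,
    )


def simulate_dataset(model: KineticModel, config: SimulationConfig) -> Dataset:
    """Simulate a full dataset of ``config.n_traces`` molecules.

    Deterministic given (model, config): per-trace RNG substreams are
    derived from ``(config.seed, trace index)`` so any trace can be
    regenerated independently.  Traces that would be shorter than one
    frame are redrawn.
    """
    model = validate_model(model)
    if config.emission_means is None or config.emission_cov is None:
        raise ValueError("config must define emission_means and emission_cov")
    if config.emission_means.shape[0] != model.n_states:
        raise ValueError("emission_means rows must match n_states")
    traces, paths, factors = [], [], []
    for i in range(config.n_traces):
        rng = np.random.default_rng([int(config.seed), i])
        trace = None
        for _attempt in range(100):
            duration = draw_trace_length(
                config.bleach_rate, config.min_length, config.max_length, rng
            )
            if int(np.floor(duration * config.sampling_rate)) < 1:
                continue
            path = simulate_state_path(model, duration, rng)
            occ = discretize_path(path, config.sampling_rate)
            if occ.shape[1] < model.n_states:  # states never visited: pad columns
                occ = np.pad(occ, ((0, 0), (0, model.n_states - occ.shape[1])))
            means = (
                perturb_state_means(config.emission_means, config.mean_jitter_scale, rng)
                if config.enable_mean_jitter
                else config.emission_means
            )
            brightness = (
                draw_brightness_factor(config.brightness_base, rng)
                if config.enable_brightness
                else 1.0
            )
            d_dark = a_dark = None
            if config.enable_blinking:
                d_dark = simulate_blinking(duration, *config.blink_rates["donor"], rng)
                a_dark = simulate_blinking(duration, *config.blink_rates["acceptor"], rng)
            trace = emit_trace(
                occ,
                means,
                config.emission_cov,
                rng,
                donor_dark=d_dark,
                acceptor_dark=a_dark,
                sampling_rate=config.sampling_rate,
                brightness=brightness,
                trace_id=f"trace{i:04d}",
            )
            paths.append(path)
            factors.append({"means": means, "brightness": brightness})
            break
        if trace is None:
            raise RuntimeError(f"could not draw a usable trace for index {i}")
        traces.append(trace)
    return Dataset(
        traces=traces,
        sampling_rate=config.sampling_rate,
        gt_model=model,
        gt_paths=paths,
        gt_factors=factors,
        seed=config.seed,
    )
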