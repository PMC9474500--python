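"""Reference kinetic inference from smFRET traces.

The workflow is the common denominator of HMM-based smFRET analysis
tools: a single Gaussian-emission hidden Markov model over the FRET
efficiency is fit jointly to all traces of a dataset (ensemble
Baum-Welch, shared parameters, per-trace forward-backward statistics),
the Viterbi algorithm yields idealized state sequences, dwell times are
compiled per transition, and the per-frame transition probability
matrix is converted to rate constants via the principal matrix
logarithm.  Model size is selected by BIC and uncertainties come from a
parametric bootstrap that re-simulates datasets from the inferred model
and refits them.

An optional tied-emission mode shares Gaussian parameters between
designated hidden states, which lets the HMM resolve kinetic
heterogeneity: states that are indistinguishable by FRET efficiency but
differ in kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from scipy.linalg import logm
from sklearn.cluster import KMeans

from .models import KineticModel
from .simulate import discretize_path, simulate_state_path


class InferenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# dwell containers


@dataclass
class DwellSet:
    """Censoring-annotated dwell times from idealized state sequences.

    ``records`` columns: state (from-state), to_state (destination, -1
    for censored dwells), duration (s), censored (bool), trace_id.
    Durations are positive integer multiples of ``frame_period``.
    """

    records: pd.DataFrame
    frame_period: float

    def uncensored(self, state: int | None = None, to_state: int | None = None) -> np.ndarray:
        """Uncensored dwell durations, optionally filtered by transition."""
        r = self.records[~self.records.censored]
        if state is not None:
            r = r[r.state == state]
        if to_state is not None:
            r = r[r.to_state == to_state]
        return r.duration.to_numpy()


# ---------------------------------------------------------------------------
# HMM machinery


class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that retains the complete log-likelihood path."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


class TiedGaussianHMM(GaussianHMM):
    """GaussianHMM whose emission parameters can be tied across states.

    ``tie_groups`` is a list of index lists; all states in a group share
    one emission mean and variance, re-estimated from the pooled
    sufficient statistics each M-step.
    """

    def __init__(self, *args, tie_groups=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.tie_groups = tie_groups

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        if not self.tie_groups:
            return
        for group in self.tie_groups:
            g = np.asarray(group)
            post = stats["post"][g].sum()
            if post <= 0:
                continue
            mean = stats["obs"][g].sum(axis=0) / post
            var = (
                stats["obs**2"][g].sum(axis=0)
                - 2 * mean * stats["obs"][g].sum(axis=0)
                + mean**2 * post
            ) / post
            if "m" in self.params:
                self.means_[g] = mean
            if "c" in self.params:
                self._covars_[g] = np.maximum(var, self.min_covar)


@dataclass
class InferredModel:
    """An ensemble-HMM fit: emission parameters, kinetics and diagnostics."""

    n_states: int
    fret_means: np.ndarray
    fret_sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    rates: np.ndarray
    rate_method: str
    log_likelihood: float
    bic: float
    n_frames: int
    frame_period: float
    converged: bool
    n_iter: int
    logl_history: list = field(default_factory=list)
    ci95: dict | None = None
    tie_groups: list | None = None
    rates_linear: np.ndarray | None = None  # P/dt fallback, kept when it disagrees

    def to_kinetic_model(self) -> KineticModel:
        """Express the fit as a kinetic model (rates + FRET efficiencies)."""
        return KineticModel(rates=self.rates.copy(), fret=self.fret_means.copy())

    def _to_hmm(self) -> GaussianHMM:
        h = GaussianHMM(
            n_components=self.n_states, covariance_type="diag", min_covar=1e-8, init_params=""
        )
        h.n_features = 1
        h.startprob_ = self.startprob.copy()
        h.transmat_ = self.transmat.copy()
        h.means_ = self.fret_means.reshape(-1, 1).copy()
        h.covars_ = (self.fret_sds**2).reshape(-1, 1).copy()
        return h


def _photophysics_mask(trace, fraction: float = 0.3) -> np.ndarray:
    """True for frames to keep; dye-dark frames are excluded.

    Acceptor dark states are flagged by a collapsed direct-excitation
    acceptor signal (the standard alternating-excitation check) and
    donor dark states by a collapsed total intensity; both thresholds
    are ``fraction`` of the per-trace median.  Traces without an
    informative acceptor-direct channel skip the first check.
    """
    keep = np.ones(trace.n_frames, dtype=bool)
    ad = np.asarray(trace.acceptor_direct, dtype=float)
    if ad.size and np.nanmedian(ad) > 0:
        keep &= ad >= fraction * np.nanmedian(ad)
    total = np.asarray(trace.donor, dtype=float) + np.asarray(trace.acceptor, dtype=float)
    med = np.nanmedian(total)
    if med > 0:
        keep &= total >= fraction * med
    return keep


def _finite_sequences(traces):
    """Concatenate usable FRET frames; masked frames split sequences.

    Frames are dropped when the FRET efficiency is undefined or the
    photophysics mask flags them as dye-dark.  Returns (X column
    vector, lengths, per-trace frame maps) where each map holds (start
    offset in X, slice of original frame indices) per contiguous kept
    run.
    """
    chunks, lengths, maps = [], [], []
    offset = 0
    for trace in traces:
        fret = np.asarray(trace.fret, dtype=float)
        finite = np.isfinite(fret) & _photophysics_mask(trace)
        runs = []
        i = 0
        while i < len(fret):
            if not finite[i]:
                i += 1
                continue
            j = i
            while j < len(fret) and finite[j]:
                j += 1
            chunks.append(fret[i:j])
            lengths.append(j - i)
            runs.append((offset, i, j))
            offset += j - i
            i = j
        maps.append(runs)
    if not chunks:
        raise InferenceError("no finite FRET frames in dataset")
    x = np.concatenate(chunks).reshape(-1, 1)
    return x, np.array(lengths), maps


def kmeans_state_assignment(traces, n_states: int, seed: int = 0):
    """Cluster pooled FRET values with k-means.

    Returns (labels over pooled finite frames, cluster means ascending).
    States are relabeled so cluster means increase with the label.
    """
    x, _, _ = _finite_sequences(traces)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if len(np.unique(x)) < n_states:
        raise InferenceError(f"fewer than {n_states} distinct FRET values")
    if n_states == 1:
        return np.zeros(len(x), dtype=int), np.array([float(x.mean())])
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    return relabel[km.labels_], km.cluster_centers_[order, 0]


def _initial_params(x, labels, means, n_states, rng, jitter=0.0):
    mu = means + (rng.uniform(-jitter, jitter, size=n_states) if jitter else 0.0)
    sds = np.empty(n_states)
    freqs = np.empty(n_states)
    pooled_sd = max(float(x.std()), 1e-3)
    for s in range(n_states):
        sel = x[labels == s, 0]
        sds[s] = sel.std() if len(sel) > 1 else pooled_sd
        freqs[s] = max(len(sel), 1)
    sds = np.maximum(sds, 1e-3)
    freqs = freqs / freqs.sum()
    transmat = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.95)
    transmat /= transmat.sum(axis=1, keepdims=True)
    return mu, sds, freqs, transmat


def fit_ensemble_hmm(
    traces,
    n_states: int,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    tie_groups: list | None = None,
    init_means: np.ndarray | None = None,
) -> InferredModel:
    """Fit one Gaussian-emission HMM jointly to all traces.

    Baum-Welch EM with a single shared parameter set; per-trace
    forward-backward statistics are accumulated across traces.  Frames
    with undefined FRET efficiency are masked out of the likelihood.
    Initialisation uses k-means cluster means (per-cluster SDs, 0.95
    diagonal transition matrix); restarts jitter the means by up to
    0.02 and the best log-likelihood wins.  States are relabeled in
    ascending FRET-mean order.
    """
    if not traces or all(t.n_frames < 2 for t in traces):
        raise InferenceError("need at least one trace with two or more frames")
    x, lengths, _ = _finite_sequences(traces)
    frame_period = 1.0 / traces[0].sampling_rate
    if tie_groups is None:
        labels, km_means = kmeans_state_assignment(traces, n_states, seed=seed)
    else:
        # with tied emissions, cluster at the emission-class level then replicate
        n_classes = len(tie_groups)
        cls_labels, cls_means = kmeans_state_assignment(traces, n_classes, seed=seed)
        km_means = np.empty(n_states)
        for c, group in enumerate(tie_groups):
            km_means[np.asarray(group)] = cls_means[c]
        labels = np.empty(len(x), dtype=int)
        for c, group in enumerate(tie_groups):
            labels[cls_labels == c] = group[0]

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(n_restarts, 1)):
        jitter = 0.0 if restart == 0 else 0.02
        mu, sds, freqs, transmat = _initial_params(x, labels, km_means, n_states, rng, jitter)
        if init_means is not None and restart == 0:
            mu = np.asarray(init_means, dtype=float)
        if tie_groups:
            # keep the start point inside the tied family (EM stays monotone);
            # asymmetric per-state exit probabilities break the within-group symmetry
            for group in tie_groups:
                g = np.asarray(group)
                mu[g] = mu[g].mean()
                sds[g] = sds[g].mean()
                freqs[g] = freqs[g].mean()
                for rank, s in enumerate(group):
                    stay = 0.99 - 0.09 * rank
                    transmat[s] = (1 - stay) / (n_states - 1)
                    transmat[s, s] = stay
            freqs = freqs / freqs.sum()
        hmm_cls = TiedGaussianHMM if tie_groups else GaussianHMM
        kwargs = {"tie_groups": tie_groups} if tie_groups else {}
        h = hmm_cls(
            n_components=n_states,
            covariance_type="diag",
            min_covar=1e-8,
            covars_prior=0.0,
            n_iter=max_iter,
            tol=tol,
            init_params="",
            random_state=int(rng.integers(2**31)),
            **kwargs,
        )
        h.monitor_ = _FullHistoryMonitor(h.tol, h.n_iter, h.verbose)
        h.startprob_ = freqs
        h.transmat_ = transmat
        h.means_ = mu.reshape(-1, 1)
        h.covars_ = (sds**2).reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h.fit(x, lengths)
        logl = h.monitor_.full_history[-1]
        if not np.isfinite(logl):
            raise InferenceError(
                f"non-finite likelihood at restart {restart}, "
                f"iteration {len(h.monitor_.full_history)}"
            )
        if best is None or logl > best[0]:
            best = (logl, h)
    logl, h = best

    order = np.argsort(h.means_[:, 0], kind="stable")
    perm = np.ix_(order, order)
    transmat = h.transmat_[perm]
    means = h.means_[order, 0]
    sds = np.sqrt(np.array(h.covars_).reshape(n_states, -1)[order, 0])
    startprob = h.startprob_[order]
    tied_sorted = None
    if tie_groups:
        inv = np.empty(n_states, dtype=int)
        inv[order] = np.arange(n_states)
        tied_sorted = [sorted(int(inv[s]) for s in g) for g in tie_groups]

    rates, method, rates_lin = transition_probs_to_rates(
        transmat, frame_period, return_fallback=True
    )
    n_frames = int(len(x))
    n_params = count_free_parameters(n_states, tie_groups=tied_sorted)
    return InferredModel(
        n_states=n_states,
        fret_means=means,
        fret_sds=sds,
        transmat=transmat,
        startprob=startprob,
        rates=rates,
        rate_method=method,
        log_likelihood=float(logl),
        bic=bic(float(logl), n_params, n_frames),
        n_frames=n_frames,
        frame_period=frame_period,
        converged=bool(h.monitor_.converged),
        n_iter=len(h.monitor_.full_history),
        logl_history=list(h.monitor_.full_history),
        tie_groups=tied_sorted,
        rates_linear=rates_lin,
    )


def viterbi_paths(inferred: InferredModel, traces) -> list[np.ndarray]:
    """Most probable (Viterbi) state sequence per trace.

    Frames with undefined FRET efficiency are marked -1; each contiguous
    finite run is decoded independently.
    """
    h = inferred._to_hmm()
    x, _, maps = _finite_sequences(traces)
    out = []
    for trace, runs in zip(traces, maps):
        path = np.full(trace.n_frames, -1, dtype=int)
        for off, i, j in runs:
            _, seq = h.decode(x[off : off + (j - i)], algorithm="viterbi")
            path[i:j] = seq
        out.append(path)
    return out


def extract_dwells(paths: list[np.ndarray], frame_period: float) -> DwellSet:
    """Compile dwell times from idealized state sequences.

    One record per constant-state run.  The first and last run of every
    trace (and runs bordering undefined stretches) are censored: their
    true duration is unknown because the observation window, not a
    transition, ends them.
    """
    rows = []
    for t, path in enumerate(paths):
        trace_id = f"trace{t:04d}"
        i = 0
        n = len(path)
        while i < n:
            if path[i] < 0:
                i += 1
                continue
            j = i
            while j < n and path[j] == path[i]:
                j += 1
            left_open = i == 0 or path[i - 1] < 0
            right_open = j == n or path[j] < 0
            censored = left_open or right_open
            rows.append(
                {
                    "state": int(path[i]),
                    "to_state": int(path[j]) if not right_open else -1,
                    "duration": (j - i) * frame_period,
                    "censored": censored,
                    "trace_id": trace_id,
                }
            )
            i = j
    records = pd.DataFrame(rows, columns=["state", "to_state", "duration", "censored", "trace_id"])
    return DwellSet(records=records, frame_period=frame_period)


def exponential_mle(dwells) -> float:
    """Rate-constant MLE for exponential dwells: 1 / mean dwell time."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("no dwell times given")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    return float(1.0 / d.mean())


def transition_probs_to_rates(
    P: np.ndarray, frame_period: float, return_fallback: bool = False
):
    """Convert a per-frame transition probability matrix to rates (s^-1).

    Primary route: principal matrix logarithm, ``K = logm(P)/dt``, which
    accounts for multiple transitions within one frame; negative
    off-diagonal entries (numerical artefacts) are clipped to zero and
    the diagonal rebalanced.  When the principal logarithm is not real
    the element-wise fallback ``k_ij = P_ij/dt`` is used instead.  The
    fallback is also returned (``rates_linear``) whenever it differs
    from the primary estimate by more than 5% on any rate.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-8):
        raise ValueError("P must be row-stochastic")
    if frame_period <= 0:
        raise ValueError("frame_period must be positive")
    n = P.shape[0]
    linear = P / frame_period
    np.fill_diagonal(linear, 0.0)
    method = "matrix_log"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            L = logm(P)
        if np.max(np.abs(L.imag)) > 1e-8:
            raise ValueError("complex branch")
        K = L.real / frame_period
        off = ~np.eye(n, dtype=bool)
        K[off] = np.clip(K[off], 0.0, None)
        np.fill_diagonal(K, 0.0)
    except Exception:
        K = linear.copy()
        method = "linear"
    keep_fallback = method == "linear"
    if method == "matrix_log":
        denom = np.where(K > 0, K, np.inf)
        if np.any(np.abs(K - linear) / denom > 0.05):
            keep_fallback = True
    if return_fallback:
        return K, method, (linear if keep_fallback else None)
    return K, method


def count_free_parameters(n_states: int, tie_groups: list | None = None) -> int:
    """Free parameters of the ensemble HMM.

    Counted as: emission means + emission SDs (one pair per tied group
    if emissions are tied, else per state) + n*(n-1) free transition
    probabilities + (n-1) free initial probabilities.
    """
    n_emission = 2 * (len(tie_groups) if tie_groups else n_states)
    return n_emission + n_states * (n_states - 1) + (n_states - 1)


def bic(logL: float, n_params: int, n_frames: int) -> float:
    """Bayesian information criterion: -2 logL + p ln(N)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return -2.0 * logL + n_params * np.log(n_frames)


def _min_pairwise_snr(means: np.ndarray, sds: np.ndarray) -> float:
    n = len(means)
    if n < 2:
        return np.inf
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            best = min(best, abs(means[i] - means[j]) / np.hypot(sds[i], sds[j]))
    return best


def select_model(
    traces,
    max_states: int,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    min_state_snr: float = 1.0,
) -> InferredModel:
    """Fit 1..max_states hidden states and return the minimum-BIC model.

    Candidates whose fitted emission means are not spectroscopically
    resolvable — any state pair with ``|mu_i - mu_j| /
    sqrt(s_i^2 + s_j^2) < min_state_snr`` — are excluded: such extra
    states typically absorb camera-blurred transition frames rather
    than genuine conformations (an equal-weight Gaussian pair becomes
    unimodal below separation sqrt(2), so the default of 1 is
    conservative).  States sharing one FRET efficiency but differing in
    kinetics are reachable only through explicit tied-emission fits.

    The full BIC table is attached as ``model.bic_table``; per-candidate
    fit failures are recorded there and are fatal only if every
    candidate fails.
    """
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    candidates, table = {}, []
    for k in range(1, max_states + 1):
        try:
            m = fit_ensemble_hmm(
                traces, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed
            )
            snr = _min_pairwise_snr(m.fret_means, m.fret_sds)
            if snr < min_state_snr:
                table.append(
                    {
                        "n_states": k,
                        "bic": np.inf,
                        "logL": m.log_likelihood,
                        "error": f"states not resolvable (min pairwise SNR {snr:.2f})",
                    }
                )
                continue
            candidates[k] = m
            table.append({"n_states": k, "bic": m.bic, "logL": m.log_likelihood, "error": None})
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            table.append({"n_states": k, "bic": np.inf, "logL": np.nan, "error": str(exc)})
    if not candidates:
        raise InferenceError(f"all candidate fits failed: {table}")
    best = min(candidates.values(), key=lambda m: m.bic)
    best.bic_table = pd.DataFrame(table)
    return best


def _resimulate_fret(inferred: InferredModel, durations, sampling_rate, rng):
    """Generate FRET-only traces from an inferred model (for the bootstrap).

    Re-simulates continuous-time paths at the inferred rates, discretises
    at the original frame rate and emits occupancy-weighted Gaussian
    FRET values — the generative process the HMM assumes, driven by the
    inferred kinetics.
    """
    from .simulate import Trace  # local import to avoid cycle at module load

    model = KineticModel(rates=inferred.rates.copy(), fret=inferred.fret_means.copy())
    traces = []
    for d in durations:
        path = simulate_state_path(model, d, rng)
        occ = discretize_path(path, sampling_rate)
        if occ.shape[1] < model.n_states:
            occ = np.pad(occ, ((0, 0), (0, model.n_states - occ.shape[1])))
        draws = rng.normal(
            inferred.fret_means[None, :], inferred.fret_sds[None, :], size=occ.shape
        )
        fret = (occ * draws).sum(axis=1)
        n = len(fret)
        traces.append(
            Trace(
                times=np.arange(n) / sampling_rate,
                donor=1.0 - fret,
                acceptor=fret.copy(),
                acceptor_direct=np.zeros(n),
                fret=fret,
                sampling_rate=sampling_rate,
            )
        )
    return traces


def bootstrap_ci(
    inferred: InferredModel,
    traces,
    n_boot: int = 100,
    level: float = 95.0,
    seed: int = 0,
    max_iter: int = 200,
    n_restarts: int = 1,
) -> dict:
    """Parametric-bootstrap confidence intervals for the rate constants.

    Re-simulates ``n_boot`` datasets from the inferred model at matched
    trace count and lengths, refits each with the same state count, and
    reports percentile intervals of the refit rates.  Refit failures are
    dropped (their count is reported).  The result maps ``(i, j)`` to
    ``(low, high)`` and carries the raw samples under ``"samples"``.
    """
    if n_boot < 10:
        warnings.warn("n_boot < 10 gives unstable percentile intervals", stacklevel=2)
    sampling_rate = 1.0 / inferred.frame_period
    durations = [t.n_frames / sampling_rate for t in traces]
    rng = np.random.default_rng(seed)
    samples, failures = [], 0
    for _ in range(n_boot):
        boot_traces = _resimulate_fret(inferred, durations, sampling_rate, rng)
        try:
            refit = fit_ensemble_hmm(
                boot_traces,
                inferred.n_states,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=1e-5,
                seed=int(rng.integers(2**31)),
                tie_groups=inferred.tie_groups,
                init_means=inferred.fret_means,
            )
            samples.append(refit.rates)
        except Exception:  # noqa: BLE001 - dropped with count
            failures += 1
    if not samples:
        raise InferenceError("all bootstrap refits failed")
    arr = np.array(samples)
    alpha = (100.0 - level) / 2.0
    ci = {"samples": arr, "n_failures": failures, "level": level}
    n = inferred.n_states
    for i in range(n):
        for j in range(n):
            if i != j:
                lo, hi = np.percentile(arr[:, i, j], [alpha, 100.0 - alpha])
                ci[(i, j)] = (float(lo), float(hi))
    inferred.ci95 = ci
    return ci
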