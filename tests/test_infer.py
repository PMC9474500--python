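"""Ensemble-HMM inference: fitting, Viterbi, dwells, rate conversion, BIC."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import fretbench as fb
from fretbench.infer import InferenceError, InferredModel, count_free_parameters
from fretbench.simulate import Trace


def fret_trace(values, rate=5.0):
    v = np.asarray(values, dtype=float)
    return Trace(
        times=np.arange(len(v)) / rate,
        donor=1 - v,
        acceptor=v.copy(),
        acceptor_direct=np.zeros(len(v)),
        fret=v.copy(),
        sampling_rate=rate,
    )


def manual_model(means, sds, transmat, startprob, rate=5.0):
    means = np.asarray(means, float)
    n = len(means)
    rates, method = fb.transition_probs_to_rates(np.asarray(transmat, float), 1.0 / rate)
    return InferredModel(
        n_states=n,
        fret_means=means,
        fret_sds=np.asarray(sds, float),
        transmat=np.asarray(transmat, float),
        startprob=np.asarray(startprob, float),
        rates=rates,
        rate_method=method,
        log_likelihood=0.0,
        bic=0.0,
        n_frames=0,
        frame_period=1.0 / rate,
        converged=True,
        n_iter=0,
    )


class TestKmeansAssignment:
    def test_agrees_with_midpoint_threshold_oracle(self):
        rng = np.random.default_rng(0)
        e = np.concatenate([rng.normal(0.3, 0.05, 3000), rng.normal(0.7, 0.05, 3000)])
        labels, means = fb.kmeans_state_assignment([fret_trace(e)], 2, seed=0)
        oracle = (e > 0.5).astype(int)
        assert np.mean(labels == oracle) >= 0.99
        assert np.allclose(means, [0.3, 0.7], atol=0.02)

    def test_single_cluster_is_pooled_mean(self):
        e = np.random.default_rng(1).normal(0.5, 0.05, 500)
        labels, means = fb.kmeans_state_assignment([fret_trace(e)], 1)
        assert np.all(labels == 0)
        assert means[0] == pytest.approx(e.mean())

    def test_too_many_clusters_rejected(self):
        with pytest.raises(InferenceError, match="distinct"):
            fb.kmeans_state_assignment([fret_trace([0.5, 0.5, 0.5])], 2)


class TestFitEnsembleHmm:
    def test_recovers_archetype_parameters(self, small_archetype_dataset):
        model, _, dataset = small_archetype_dataset
        fit = fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=2, seed=0)
        assert np.allclose(fit.fret_means, model.fret, atol=0.02)
        dev = fb.percent_deviation(fit.to_kinetic_model(), model)
        assert dev.max_rate_deviation < 15.0

    def test_single_state_data_has_sticky_self_transitions(self):
        rng = np.random.default_rng(2)
        traces = [fret_trace(rng.normal(0.5, 0.05, 400)) for _ in range(3)]
        fit = fb.fit_ensemble_hmm(traces, 1, n_restarts=1, seed=0, max_iter=100)
        assert np.diag(fit.transmat).min() >= 0.99
        assert np.allclose(fit.rates, 0.0)

    def test_loglikelihood_monotone_nondecreasing(self, small_archetype_dataset):
        _, _, dataset = small_archetype_dataset
        fit = fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=1, seed=3)
        assert np.all(np.diff(fit.logl_history) > -1e-8 * np.abs(fit.logl_history[0]))

    def test_transition_rows_sum_to_one(self, small_archetype_dataset):
        _, _, dataset = small_archetype_dataset
        fit = fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=1, seed=4)
        assert np.abs(fit.transmat.sum(axis=1) - 1).max() < 1e-10
        assert fit.rates[~np.eye(2, dtype=bool)].min() >= 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(InferenceError):
            fb.fit_ensemble_hmm([], 2)

    def test_undefined_fret_frames_are_masked(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0.5, 0.05, 300)
        e[::17] = np.nan
        fit = fb.fit_ensemble_hmm([fret_trace(e)], 1, n_restarts=1)
        assert fit.n_frames == np.isfinite(e).sum()


def brute_force_viterbi(x, means, sds, transmat, startprob):
    """Exhaustive maximum-probability path over all state sequences."""
    n = len(means)
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=len(x)):
        logp = np.log(startprob[path[0]])
        for a, b in zip(path, path[1:]):
            logp += np.log(transmat[a, b])
        for s, xi in zip(path, x):
            logp += -0.5 * ((xi - means[s]) / sds[s]) ** 2 - np.log(
                sds[s] * np.sqrt(2 * np.pi)
            )
        if logp > best_logp:
            best_logp, best_path = logp, path
    return np.array(best_path), best_logp


class TestViterbi:
    def test_noiseless_two_level_trace_recovers_generating_path(self):
        path = np.array([0, 0, 0, 1, 1, 0, 1, 1, 1, 0])
        e = np.where(path == 1, 0.7, 0.3) + np.random.default_rng(6).normal(0, 1e-4, 10)
        m = manual_model([0.3, 0.7], [0.05, 0.05], [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        out = fb.viterbi_paths(m, [fret_trace(e)])[0]
        assert np.array_equal(out, path)

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 4))
            length = int(rng.integers(2, 13))
            means = np.sort(rng.uniform(0, 1, n))
            sds = rng.uniform(0.03, 0.15, n)
            transmat = rng.dirichlet(np.ones(n) * 2, size=n)
            startprob = rng.dirichlet(np.ones(n))
            x = rng.uniform(-0.2, 1.2, length)
            m = manual_model(means, sds, transmat, startprob)
            out = fb.viterbi_paths(m, [fret_trace(x)])[0]
            oracle, _ = brute_force_viterbi(x, means, sds, transmat, startprob)
            assert np.array_equal(out, oracle)

    def test_uniform_emissions_give_most_probable_constant_path(self):
        # identical emissions: the sticky state with higher start prob wins
        m = manual_model(
            [0.5, 0.5], [0.1, 0.1], [[0.99, 0.01], [0.2, 0.8]], [0.7, 0.3]
        )
        out = fb.viterbi_paths(m, [fret_trace(np.full(20, 0.5))])[0]
        assert np.all(out == 0)


class TestExtractDwells:
    def test_boundary_runs_are_censored(self):
        ds = fb.extract_dwells([np.array([0, 0, 0, 1, 1, 1])], 0.2)
        assert len(ds.records) == 2
        assert ds.records.censored.all()
        assert np.allclose(ds.records.duration, 0.6)
        assert len(ds.uncensored()) == 0

    def test_single_interior_dwell_counted(self):
        ds = fb.extract_dwells([np.array([0, 0, 0, 1, 1, 1, 0, 0])], 0.2)
        unc = ds.records[~ds.records.censored]
        assert len(unc) == 1
        row = unc.iloc[0]
        assert (row.state, row.to_state) == (1, 0)
        assert row.duration == pytest.approx(0.6)

    def test_run_lengths_conserve_total_frames(self):
        rng = np.random.default_rng(8)
        paths = [rng.integers(0, 3, rng.integers(5, 50)) for _ in range(20)]
        ds = fb.extract_dwells(paths, 0.1)
        assert ds.records.duration.sum() == pytest.approx(
            sum(len(p) for p in paths) * 0.1
        )

    def test_undefined_frames_censor_adjacent_runs(self):
        ds = fb.extract_dwells([np.array([0, 0, -1, 1, 1, 0, 0])], 1.0)
        # runs: [0,0] censored(left), [1,1] censored (borders gap), [0,0] censored(right)
        assert ds.records.censored.all()


class TestExponentialMle:
    @pytest.mark.parametrize("dwells,expected", [([1.0, 1.0, 1.0], 1.0), ([0.5, 1.5], 1.0)])
    def test_inverse_mean(self, dwells, expected):
        assert fb.exponential_mle(dwells) == pytest.approx(expected)

    def test_monte_carlo_consistency(self):
        d = np.random.default_rng(9).exponential(0.5, 100_000)
        assert fb.exponential_mle(d) == pytest.approx(2.0, abs=0.02)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fb.exponential_mle([])
        with pytest.raises(ValueError):
            fb.exponential_mle([1.0, 0.0])


class TestRateConversion:
    def test_identity_matrix_gives_zero_rates(self):
        rates, method = fb.transition_probs_to_rates(np.eye(3), 0.2)
        assert np.allclose(rates, 0.0)
        assert method == "matrix_log"

    def test_matches_analytic_two_state_matrix_log(self):
        # independent closed form: logm(P) = -ln(lambda)/(p+q) * (P - I)
        # where lambda = 1 - p - q is the second eigenvalue
        p, q, dt = 0.02, 0.04, 0.2
        P = np.array([[1 - p, p], [q, 1 - q]])
        lam = 1 - p - q
        oracle = (-np.log(lam) / (p + q)) * (P - np.eye(2)) / dt
        rates, method = fb.transition_probs_to_rates(P, dt)
        assert method == "matrix_log"
        assert rates[0, 1] == pytest.approx(oracle[0, 1], rel=1e-10)
        assert rates[1, 0] == pytest.approx(oracle[1, 0], rel=1e-10)

    def test_round_trip_through_matrix_exponential(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(2, 4))
            K = rng.uniform(0.05, 1.0, (n, n))
            np.fill_diagonal(K, 0.0)
            Q = K.copy()
            np.fill_diagonal(Q, -K.sum(axis=1))
            dt = 0.2
            P = expm(Q * dt)
            rates, _ = fb.transition_probs_to_rates(P, dt)
            assert np.allclose(rates, K, atol=1e-8)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            fb.transition_probs_to_rates(np.array([[0.5, 0.6], [0.1, 0.9]]), 0.2)


class TestBicAndSelection:
    def test_zero_parameters_zero_loglik(self):
        assert fb.bic(0.0, 0, 10) == 0.0

    def test_penalty_arithmetic(self):
        assert fb.bic(-100.0, 4, int(np.e**2) + 1) == pytest.approx(200 + 8, rel=0.01)

    def test_parameter_count_documented_formula(self):
        # n means + n sds + n(n-1) transitions + (n-1) initial probs
        assert count_free_parameters(2) == 2 + 2 + 2 + 1
        assert count_free_parameters(3) == 3 + 3 + 6 + 2
        assert count_free_parameters(4, tie_groups=[[0, 1], [2, 3]]) == 2 + 2 + 12 + 3

    def test_selects_two_states_on_two_state_data(self, small_archetype_dataset):
        _, _, dataset = small_archetype_dataset
        best = fb.select_model(dataset.traces, max_states=3, n_restarts=2, seed=0)
        assert best.n_states == 2
        assert best.bic_table.bic.idxmin() == 1


class TestBootstrapCi:
    def test_interval_covers_truth_on_well_determined_problem(
        self, small_archetype_dataset
    ):
        model, _, dataset = small_archetype_dataset
        fit = fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=1, seed=1)
        ci = fb.bootstrap_ci(fit, dataset.traces, n_boot=30, seed=1)
        assert ci["n_failures"] == 0
        lo, hi = ci[(0, 1)]
        assert lo <= fit.rates[0, 1] <= hi or abs(fit.rates[0, 1] - lo) < 0.02
        assert lo <= model.rates[0, 1] <= hi
        lo, hi = ci[(1, 0)]
        assert lo <= model.rates[1, 0] <= hi

    def test_width_shrinks_with_dataset_size(self, two_state_model):
        _, config = fb.presets.two_state_archetype(seed=31)
        widths = []
        for n_traces in (6, 24):
            config.n_traces = n_traces
            ds = fb.simulate_dataset(two_state_model, config)
            fit = fb.fit_ensemble_hmm(ds.traces, 2, n_restarts=1, seed=2)
            ci = fb.bootstrap_ci(fit, ds.traces, n_boot=25, seed=2)
            widths.append(ci[(0, 1)][1] - ci[(0, 1)][0])
        # factor-4 data: width should drop roughly like 1/sqrt(n), +-30% slack
        assert widths[1] < widths[0]
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.5)

    def test_small_n_boot_warns(self, small_archetype_dataset):
        _, _, dataset = small_archetype_dataset
        fit = fb.fit_ensemble_hmm(dataset.traces[:3], 2, n_restarts=1, seed=3)
        with pytest.warns(UserWarning, match="n_boot"):
            fb.bootstrap_ci(fit, dataset.traces[:3], n_boot=5, seed=3)


class TestKineticHeterogeneity:
    def test_tied_four_state_model_reproduces_dwell_cdf_better(self):
        model, config = fb.presets.heterogeneous_four_state(seed=3)
        config.n_traces = 120
        dataset = fb.simulate_dataset(model, config)
        fit2 = fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=2, seed=0)
        fit4 = fb.fit_ensemble_hmm(
            dataset.traces, 4, n_restarts=2, seed=0, tie_groups=[[0, 1], [2, 3]]
        )
        rng = np.random.default_rng(0)
        kw = dict(oversample_factor=20, reference_points=10_000, sampling_rate=5.0)
        cdf_gt = fb.cumulative_dwell_cdf(model, rng=rng, **kw)
        cdf2 = fb.cumulative_dwell_cdf(fit2.to_kinetic_model(), rng=rng, **kw)
        cdf4 = fb.cumulative_dwell_cdf(fit4.to_kinetic_model(), rng=rng, **kw)
        for cls in (0, 1):
            assert cdf_gt.sup_distance(cdf4, cls) < cdf_gt.sup_distance(cdf2, cls)

    def test_emission_selection_sees_two_apparent_states(self):
        # with emissions as the only evidence, BIC favours the two visible
        # FRET states over spurious extra emission levels
        model, config = fb.presets.heterogeneous_four_state(seed=5)
        config.n_traces = 60
        dataset = fb.simulate_dataset(model, config)
        best = fb.select_model(dataset.traces, max_states=3, n_restarts=2, seed=0)
        assert best.n_states == 2
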