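import numpy as np
import pytest

import fretbench as fb


@pytest.fixture(scope="session")
def two_state_model():
    model, _ = fb.presets.two_state_archetype()
    return model


@pytest.fixture(scope="session")
def small_archetype_dataset():
    """Reduced-size two-state dataset for fast unit tests (~12k frames)."""
    model, config = fb.presets.two_state_archetype(seed=11)
    config.n_traces = 15
    return model, config, fb.simulate_dataset(model, config)


@pytest.fixture(scope="session")
def full_archetype_dataset():
    """Full-scale two-state benchmark dataset (75 traces, ~60k frames)."""
    model, config = fb.presets.two_state_archetype(seed=2026)
    return model, config, fb.simulate_dataset(model, config)


@pytest.fixture(scope="session")
def full_archetype_fit(full_archetype_dataset):
    _, _, dataset = full_archetype_dataset
    return fb.fit_ensemble_hmm(dataset.traces, 2, n_restarts=3, seed=7)


def random_irreducible_model(rng, n_states=None):
    """A random valid kinetic model with all off-diagonal rates positive."""
    n = n_states or rng.integers(2, 5)
    rates = rng.uniform(0.05, 2.0, size=(n, n))
    np.fill_diagonal(rates, 0.0)
    fret = np.sort(rng.uniform(0.0, 1.0, size=n))
    return fb.validate_model(fb.KineticModel(rates=rates, fret=fret))
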