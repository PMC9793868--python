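import numpy as np
import pytest

from nmfreact import (FactorizationConfig, SimulationParams, generate_ensembles,
                      generate_session)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Default study conditions: 12 neurons, 3 tiled ensembles of 4, 90 s at 20 Hz."""
    return SimulationParams(seed=7)


@pytest.fixture
def clean_session():
    """A noiseless, drift-free, clutter-free session with 3 disjoint ensembles."""
    params = SimulationParams(max_overlap=0.0, noise_sd=0.0, drift_amplitude=0.0,
                              background_rate=0.0, seed=11)
    gt = generate_ensembles(params.n_neurons, params.n_ensembles,
                            params.neurons_per_ensemble, 0.0, seed=11)
    return generate_session(gt, params, session_id="clean")


@pytest.fixture
def fast_factorization():
    """Reduced-restart settings for unit tests (restarts stand in for the
    production default of 1000)."""
    return FactorizationConfig(n_restarts=5, max_iter=300, rel_tol=1e-6,
                               rank_range=(1, 5), seed=3)
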