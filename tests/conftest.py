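import warnings

import numpy as np
import pytest

from evoland.landscape import LandscapeMeasurement
from evoland.simulate import (
    TraceConfig,
    reference_fitness_map,
    simulate_landscape_replicates,
    simulate_turbidostat_trace,
)


@pytest.fixture(scope="session")
def reference_truth():
    return reference_fitness_map()


@pytest.fixture(scope="session")
def reference_measurement(reference_truth) -> LandscapeMeasurement:
    """Replicate growth rates at the study conditions (10 reps, cv 0.1)."""
    return simulate_landscape_replicates(reference_truth, n_reps=10, cv=0.1, seed=42)


@pytest.fixture(scope="session")
def clean_trace():
    """Noiseless 24 h turbidostat sawtooth at mu = 0.3/h."""
    return simulate_turbidostat_trace(TraceConfig(true_mu=0.3, noise_sd=0.0, seed=0))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
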