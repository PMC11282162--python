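import numpy as np
import pytest

from glut4queue import DEFAULT_PARAMS, generate_synthetic_data, normalize_suite, run_protocol_suite


@pytest.fixture(scope="session")
def truth_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def small_params():
    """A small, fast network for unit tests."""
    return DEFAULT_PARAMS.replace(n_vesicles=12, n_microtubules=4, microtubule_capacity=2)


@pytest.fixture(scope="session")
def synthetic_dataset(truth_params):
    """One 7-replicate normalised dataset at the true parameters."""
    return generate_synthetic_data(truth_params, n_reps=7, seed=42)


@pytest.fixture(scope="session")
def model_table(truth_params):
    """A 25-replicate normalised model table at the true parameters."""
    return normalize_suite(run_protocol_suite(truth_params, n_runs=25, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
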