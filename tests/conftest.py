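import numpy as np
import pytest

from avihrf.hrf_core import canonical_params, hrf_response


@pytest.fixture(scope="session")
def pigeon():
    return canonical_params("pigeon")


@pytest.fixture(scope="session")
def human():
    return canonical_params("human")


@pytest.fixture(scope="session")
def pigeon_response(pigeon):
    """Fine-grid model response to the standard 2 s stimulus."""
    return hrf_response(pigeon, stim_duration=2.0, dt=0.01, t_max=30.0)


@pytest.fixture(scope="session")
def small_session():
    """One full synthetic discrimination run (session-scoped: it is reused
    by behavior, GLM and integration tests)."""
    from avihrf.synthetic_data import simulate_session

    return simulate_session(seed=20240)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654)
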