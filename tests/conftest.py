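import numpy as np
import pytest

from scandecode.paradigm import AcquisitionParams
from scandecode.preprocess import preprocess_day
from scandecode.synthsim import (
    ExperimentProtocol,
    NoiseConfig,
    make_ground_truth,
    simulate_experiment,
)

NOISELESS = NoiseConfig(sigma=0.0, drift_amplitude=0.0, global_fluct_sd=0.0, motion_coupling=0.0)


@pytest.fixture
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def truth():
    return make_ground_truth()


@pytest.fixture(scope="session")
def default_experiment(truth):
    """Full-protocol dataset at the default noise level (seed fixed)."""
    return simulate_experiment(ExperimentProtocol(), truth, seed=11)


@pytest.fixture(scope="session")
def noiseless_experiment(truth):
    return simulate_experiment(ExperimentProtocol(), truth, seed=11, noise=NOISELESS)


@pytest.fixture(scope="session")
def preprocessed_day1(default_experiment, truth):
    return preprocess_day(default_experiment.day1, truth.brain_mask)


def zero_effect_truth(grid=(10, 10, 6)):
    """Ground truth with no planted signal anywhere (null simulations)."""
    t = make_ground_truth(grid, effect_size=0.0)
    return t


def small_protocol(**kw) -> ExperimentProtocol:
    """Reduced-scale protocol for replicate-heavy tests."""
    defaults = dict(
        acquisition=AcquisitionParams(grid_shape=(10, 10, 6)),
        n_day1_runs=4,
        n_day2_alt_runs=0,
        n_day2_binary_runs=2,
    )
    defaults.update(kw)
    return ExperimentProtocol(**defaults)
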