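import numpy as np
import pytest

from cardiofit.cv_models import SolverConfig, simulate
from cardiofit.personalization import typical_parameters
from cardiofit.synthetic_data import (
    MeasurementNoise,
    ModalityModel,
    TruthSpec,
    longitudinal_truth,
    sample_cohort,
    synthesize_measurement,
)


@pytest.fixture(scope="session")
def closed_params():
    return typical_parameters("closed")


@pytest.fixture(scope="session")
def open_params():
    return typical_parameters("open")


@pytest.fixture(scope="session")
def closed_sim(closed_params):
    return simulate(closed_params, solver=SolverConfig())


@pytest.fixture(scope="session")
def open_sim(open_params):
    return simulate(open_params, solver=SolverConfig())


def _noise_free_measurement(kind, seed=11):
    spec = TruthSpec.for_kind(kind, seed=seed)
    part = sample_cohort(1, spec)[0]
    truth = longitudinal_truth(part, spec, days=("1",))["1"]
    m = synthesize_measurement(
        truth,
        part.covariates["1"],
        MeasurementNoise.none(),
        modality="carotid",
        seed=0,
        model_kind=kind,
        modality_model=ModalityModel.none(),
        participant_id=part.participant_id,
    )
    return m, truth


@pytest.fixture(scope="session")
def closed_measurement():
    """A noise-free synthetic measurement and its ground truth (closed loop)."""
    return _noise_free_measurement("closed")


@pytest.fixture(scope="session")
def open_measurement():
    return _noise_free_measurement("open")


@pytest.fixture()
def rng():
    """Fresh fixed-seed generator per test (order-independent determinism)."""
    return np.random.default_rng(20240917)
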