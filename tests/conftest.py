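import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def population():
    """Small default-parameter population shared across tests."""
    return gaitid.sample_population(gaitid.PopulationConfig(n_subjects=12, seed=11))


@pytest.fixture(scope="session")
def subject(population):
    return population[0]


@pytest.fixture(scope="session")
def sport_stride(subject):
    return gaitid.synth_grf_stride(subject, "sport", stride_seed=100)


@pytest.fixture(scope="session")
def heels_stride(subject):
    return gaitid.synth_grf_stride(subject, "heels", stride_seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_stride(
    forces,
    subject_id="S001",
    footwear="sport",
    body_weight_n=600.0,
    sampling_rate=960.0,
):
    """Hand-built stride record for formula-level tests."""
    return gaitid.StrideRecord(
        subject_id=subject_id,
        footwear=footwear,
        body_weight_n=body_weight_n,
        sampling_rate=sampling_rate,
        forces=np.asarray(forces, dtype=float),
    )
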