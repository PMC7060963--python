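import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiotransit.params import (
    IMAGING_PRESETS,
    AcquisitionParams,
    TransientParams,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_acq() -> AcquisitionParams:
    """The study's scanner configuration: 512 px, 20,000 lines, 1057.7 Hz."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionParams:
    """Two pacing epochs at reduced spatial sampling, for fast tests."""
    return AcquisitionParams(n_pixels=64, n_lines=8500)


@pytest.fixture(scope="session")
def wt_params() -> TransientParams:
    return IMAGING_PRESETS["WT"].mean_params


@pytest.fixture(scope="session")
def ko_params() -> TransientParams:
    return IMAGING_PRESETS["KO"].mean_params


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
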