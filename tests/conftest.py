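import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import exoassist as ea

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 500.0


@pytest.fixture(scope="session")
def sinusoid_params() -> ea.GaitParams:
    return ea.sinusoid_preset()


@pytest.fixture(scope="session")
def gait(sinusoid_params):
    """22 s (~20 strides) of clean sinusoid-preset walking."""
    return ea.generate_gait(sinusoid_params, 22.0)


@pytest.fixture(scope="session")
def hpt_params(sinusoid_params) -> ea.HptParams:
    return ea.HptParams(body_mass=sinusoid_params.body_mass)


@pytest.fixture(scope="session")
def src_params(sinusoid_params) -> ea.SrcParams:
    return ea.SrcParams(body_mass=sinusoid_params.body_mass)


def true_gait_fraction(time: np.ndarray, heelstrikes: np.ndarray) -> np.ndarray:
    """Ground-truth gait-cycle fraction from event times (NaN outside)."""
    p = np.full(len(time), np.nan)
    for a, b in zip(heelstrikes[:-1], heelstrikes[1:]):
        m = (time >= a) & (time < b)
        p[m] = (time[m] - a) / (b - a)
    return p


def circular_error(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Error between gait-cycle fractions on the unit circle."""
    err = est - truth
    return np.where(err > 0.5, err - 1.0, np.where(err < -0.5, err + 1.0, err))
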