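import numpy as np
import pytest

from hrvrisk.synthetic import (
    HIGH_RISK_PROFILE,
    LOW_RISK_PROFILE,
    SubjectProfile,
    simulate_rr_series,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_profile():
    """Deterministic constant-interval profile."""
    return SubjectProfile(
        group="low_risk", avnn=1.0, lf_amp=0.0, hf_amp=0.0,
        one_over_f_amp=0.0, noise_sd=0.0, ectopy_prob=0.0,
    )


@pytest.fixture(scope="session")
def low_risk_series():
    return simulate_rr_series(LOW_RISK_PROFILE, 900.0, seed=7)


@pytest.fixture(scope="session")
def high_risk_series():
    return simulate_rr_series(HIGH_RISK_PROFILE, 900.0, seed=7)
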