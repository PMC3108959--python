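import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tumorifp import TissueParameters
from tumorifp.config import baseline_config

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def baseline():
    """(tumor, normal) baseline tissue parameters from the shipped table."""
    cfg = baseline_config()
    return cfg.tissues.tumor.to_params(), cfg.tissues.normal.to_params()


@pytest.fixture(scope="session")
def tumor_baseline(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def normal_baseline(baseline):
    return baseline[1]


def make_tumor(alpha_per_cm: float, p_e: float = 1.0) -> TissueParameters:
    """Lymph-free tissue with decay rate sqrt(Lp*SV/K) = alpha_per_cm and
    effective pressure p_e (sigma=0 so p_e = pv)."""
    return TissueParameters(
        K=1.0,
        Lp=alpha_per_cm**2 / 200.0,
        SV=200.0,
        pv=p_e,
        sigma=0.0,
        pi_v=0.0,
        pi_i=0.0,
    )


def zero_source_like(params: TissueParameters) -> TissueParameters:
    """Same conductivity, no vascular or lymphatic exchange (dead tissue)."""
    return TissueParameters(
        K=params.K, Lp=0.0, SV=0.0, pv=0.0, sigma=0.0, pi_v=0.0, pi_i=0.0
    )


@pytest.fixture
def rbar_grid():
    return np.linspace(0.0, 1.0, 201)
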