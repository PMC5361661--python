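import numpy as np
import pytest

from tamoxsim.params import CYP2D6Activity, NetworkParams, ParameterSet
from tamoxsim.dosing import DoseEvent


@pytest.fixture(scope="session")
def typical_net() -> NetworkParams:
    """A literature-scale (uncalibrated) typical parameter set used by
    kinetic-core tests; values chosen for realistic half-lives
    (TAM ~5 d, NDM ~16 d, 4OH ~2.5 d, END ~2.6 d)."""
    return NetworkParams(
        ka_TAM=4.0, ka_END=12.0, F_TAM=1.0, F_END=0.85,
        V_TAM=1200.0, V_NDM=1350.0, V_4OH=1500.0, V_END=600.0,
        CLf_TAM_NDM=140.0, CLf_TAM_4OH=7.0, CLf_NDM_END=10.0,
        CLf_4OH_END=170.0, CLe_TAM=20.0, CLe_NDM=50.0, CLe_4OH=250.0,
        CLe_END=162.0)


@pytest.fixture(scope="session")
def typical_ps(typical_net) -> ParameterSet:
    return ParameterSet(typical_net, theta_IM=0.6, theta_PM=0.05,
                        cv_clearance=0.0, cv_volume=0.0)


@pytest.fixture(scope="session")
def em() -> CYP2D6Activity:
    return CYP2D6Activity("EM", 1.0)


@pytest.fixture(scope="session")
def pm() -> CYP2D6Activity:
    return CYP2D6Activity("PM", 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def daily_tam(days: int, amount: float = 20.0) -> list[DoseEvent]:
    return [DoseEvent(float(d), "TAM", amount) for d in range(1, days + 1)]
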