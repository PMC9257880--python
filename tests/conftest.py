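import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phasewalk.biomech import WalkerParams, WalkerState
from phasewalk.cpg import CPGParams, ResetMode
from phasewalk.stability import converge_forward, find_limit_cycle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: torque parameter sets reported per gait speed (A1, A2, delta)
SPEED_SETS = {0.3: (1.3, 6.1, 0.57), 0.4: (4.9, 10.0, 0.47), 0.5: (14.0, 15.0, 0.37)}


@pytest.fixture(scope="session")
def walker() -> WalkerParams:
    return WalkerParams()


@pytest.fixture(scope="session")
def v04_cycle(walker):
    """Noiseless flip-mode limit cycle at the v = 0.4 m/s parameter set."""
    cpg = CPGParams(A1=4.9, A2=10.0, delta=0.47, mode=ResetMode.FLIP)
    z = converge_forward(
        walker, cpg, WalkerState(0.131, 0.262, -0.45, -0.8), 1.2
    )
    assert z is not None, "bootstrap failed to converge to the v=0.4 cycle"
    return find_limit_cycle(walker, cpg, z)


@pytest.fixture(scope="session")
def phi0_04(v04_cycle) -> float:
    return float(v04_cycle.post_state[4])


@pytest.fixture(scope="session")
def cpg_resetting(phi0_04) -> CPGParams:
    return CPGParams(A1=4.9, A2=10.0, delta=0.47, phi0=phi0_04,
                     mode=ResetMode.RESETTING)


@pytest.fixture(scope="session")
def cpg_flip(phi0_04) -> CPGParams:
    return CPGParams(A1=4.9, A2=10.0, delta=0.47, phi0=phi0_04,
                     mode=ResetMode.FLIP)


@pytest.fixture(scope="session")
def initial_04(v04_cycle) -> WalkerState:
    y = v04_cycle.post_state
    return WalkerState(y[0], y[1], y[2], y[3])
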