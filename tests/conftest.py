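import numpy as np
import pytest

from fesreach.arm import ArmState, default_arm_params, default_muscles
from fesreach.env import ReachEnv, TaskConfig


@pytest.fixture(scope="session")
def arm_params():
    return default_arm_params()


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture
def rest_state(muscles):
    return ArmState(theta=np.deg2rad([55.0, 55.0]), omega=np.zeros(2),
                    act=np.zeros(len(muscles)))


@pytest.fixture
def env():
    return ReachEnv(seed=0)


@pytest.fixture
def big_target_env():
    """Radius so large the rest posture is already inside any target."""
    return ReachEnv(task=TaskConfig(radius=2.0), seed=0)
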