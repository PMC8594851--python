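import numpy as np
import pytest

from fvm import AgentState, ModelParams


@pytest.fixture
def params():
    """Default force-law constants (d=2, unit metric, inverse square)."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_agent(id, position, m=60.0, M=None):
    return AgentState(
        id=id,
        position=np.asarray(position, dtype=float),
        active_mass=m,
        passive_mass=m if M is None else M,
    )


@pytest.fixture
def agent_factory():
    return make_agent
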