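import numpy as np
import pytest

from featlearn.environments import FeatureSpace, build_generalizable_matrix
from featlearn.models import MODEL_SPECS, ModelSpec, ParamVector
from featlearn.tasks import build_exp12_design, build_exp34_design


@pytest.fixture(scope="session")
def space233():
    return FeatureSpace(2, 3, 2.0)


@pytest.fixture(scope="session")
def gen233(space233):
    return build_generalizable_matrix(space233)


@pytest.fixture(scope="session")
def exp1_design():
    return build_exp12_design("generalizable", 0, seed=1)


@pytest.fixture(scope="session")
def exp3_design():
    return build_exp34_design(3)


@pytest.fixture(scope="session")
def feature_decay_agent_log(exp1_design):
    """One simulated feature-based-with-decay agent on Experiment 1."""
    from featlearn.models import simulate_agent

    spec = MODEL_SPECS["feature_decay"]
    params = ParamVector(
        alpha_rew=0.3, alpha_unr=0.2, d=0.02, sigma=0.1, bias=0.0,
        w=np.array([[10.0, 10.0]]),
    )
    return simulate_agent(exp1_design, spec, params, seed=11), spec, params
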