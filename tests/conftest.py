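import numpy as np
import pytest

import mcace
from mcace import Level2Spec, LoadingSpec, ModelSpec, ParamVector


@pytest.fixture(scope="session")
def default_cfg():
    return mcace.default_scenario()


@pytest.fixture(scope="session")
def small_data(default_cfg):
    """One modest trial drawn from the default scenario."""
    data, truth = mcace.simulate_trial(default_cfg.resize(150), seed=42)
    return data, truth


@pytest.fixture(scope="session")
def toy_spec():
    """K=2 outcomes, Q=1 factor, two visits; every variance component active."""
    return ModelSpec(
        K=2,
        Q=1,
        n_visits=2,
        loading=LoadingSpec(mask=np.array([[True], [True]])),
        level2=Level2Spec(fixed_terms=(("t", "D:t"),), random_terms=(("t",),)),
    )


@pytest.fixture(scope="session")
def toy_params(toy_spec):
    return ParamVector(
        lambda0={"c": np.array([1.0, -0.5]), "n": np.array([0.6, 0.1])},
        loadings=np.array([0.9, 0.7]),
        xi={"c": np.array([0.8, 0.5]), "n": np.array([0.6, 0.9])},
        tau2={"c": np.array([1.2, 0.7]), "n": np.array([0.9, 1.1])},
        beta={"c": np.array([0.4, 1.1]), "n": np.array([0.3])},
        sigma_v=[np.array([[0.5]])],
        eta=np.array([-0.4]),
    )


@pytest.fixture(scope="session")
def ahj_cfg():
    return mcace.default_scenario("ahj_like_synthetic")
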