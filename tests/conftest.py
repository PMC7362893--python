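import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("ci")

from mlnmr import FitConfig, ScenarioConfig, build_scenario_data, fit


def pack_theta(logpost, values):
    """Build a flat parameter vector from named entries.

    Keys may be block names (``"mu"`` with an array) or single parameter
    names (``"gamma[ETN]"`` with a scalar); everything else is zero.
    """
    theta = np.zeros(logpost.ndim)
    for key, val in values.items():
        if key in logpost._slices:
            theta[logpost._slices[key]] = val
        else:
            theta[logpost.names.index(key)] = val
    return theta


@pytest.fixture(scope="session")
def scenario():
    sc = ScenarioConfig()
    sc.studies = tuple(replace(d, n_per_arm=100) for d in sc.studies)
    return sc


@pytest.fixture(scope="session")
def scenario_data(scenario):
    return build_scenario_data(scenario, seed=7, n_integration_points=512)


@pytest.fixture(scope="session")
def fe_fit(scenario, scenario_data):
    network, grids, _ = scenario_data
    cfg = FitConfig(chains=2, warmup=400, samples=400, seed=7, draws_per_chain=600)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(network, scenario.model_spec(), grids, cfg)


@pytest.fixture(scope="session")
def re_fit(scenario, scenario_data):
    network, grids, _ = scenario_data
    cfg = FitConfig(chains=2, warmup=400, samples=400, seed=11, draws_per_chain=600)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(network, scenario.model_spec(effects="random"), grids, cfg)
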