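import numpy as np
import pandas as pd
import pytest

from gfrmon import RunConfig, SimulationConfig, simulate


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort with zero measurement noise: eGFR of the generating
    equations equals measured GFR at every visit."""
    cfg = SimulationConfig(n_participants=80, attrition=0.0, mgfr_cv=0.0,
                           biomarker_cv=0.0, person_bias_sd=0.0, seed=101)
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (875 evaluable, 5% CVs, 15.9% progressors)."""
    return simulate(SimulationConfig(seed=20140401))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
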