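import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from demopair import (
    GompertzMakeham,
    StableStructure,
    build_stationary_population,
    make_life_table,
    make_stable_population,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


#: a small family of Gompertz-Makeham regimes spanning e(0) roughly 45..86
GM_FAMILY = [
    GompertzMakeham(makeham=lam, gompertz_a=a, gompertz_b=b)
    for lam in (0.0, 1e-3, 5e-3, 1e-2)
    for (a, b) in ((1e-5, 0.10), (5e-5, 0.09), (1e-4, 0.085), (2e-5, 0.11), (3e-4, 0.08), (1e-5, 0.12))
]


@pytest.fixture(scope="session")
def gm_model():
    return GompertzMakeham(makeham=0.0, gompertz_a=1e-5, gompertz_b=0.1)


@pytest.fixture(scope="session")
def gm_table(gm_model):
    return make_life_table(gm_model)


@pytest.fixture(scope="session")
def stationary_pop(gm_table):
    return build_stationary_population(gm_table, total=1000.0, time=2020)


@pytest.fixture(scope="session")
def growing_pop(gm_table):
    return make_stable_population(StableStructure(0.02, gm_table), total=1e6, time=2020)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
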