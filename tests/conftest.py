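import numpy as np
import pytest
from hypothesis import settings

import painface as pf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def zone_cfg():
    return pf.default_zone_config()


@pytest.fixture(scope="session")
def cal(zone_cfg):
    return pf.default_calibration(zone_cfg)


@pytest.fixture(scope="session")
def template(zone_cfg):
    return pf.make_template(seed=7, cfg=zone_cfg)


@pytest.fixture(scope="session")
def weight_matrix():
    return pf.default_weight_matrix()


@pytest.fixture(scope="session")
def weight_table():
    return pf.default_weight_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
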