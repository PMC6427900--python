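import numpy as np
import pytest
from hypothesis import settings as hy_settings

from angiopd.params import (SpeciesBaselines, default_baselines,
                            human_parameters, mouse_parameters)

hy_settings.register_profile("ci", derandomize=True, deadline=None)
hy_settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse_params():
    return mouse_parameters()


@pytest.fixture(scope="session")
def human_params():
    return human_parameters()


@pytest.fixture(scope="session")
def baselines() -> SpeciesBaselines:
    return default_baselines()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
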