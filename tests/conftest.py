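import warnings

import numpy as np
import pytest

from zonecast import SyntheticConfig, generate_region

# statsmodels emits convergence/interpolation warnings on tiny fixtures;
# they are expected and irrelevant to the assertions
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11,
        region_size=5000.0,
        n_schools=6,
        n_outlets_baseline=80,
        quarterly_drift=1.0,
        noise_sd=2.0,
        n_quarters=20,
        n_oa=12,
        n_lsoa=4,
        grid_spacing=500.0,
        workers_per_oa=10,
        n_stops=6,
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return generate_region(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
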