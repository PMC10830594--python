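import numpy as np
import pandas as pd
import pytest

import rosette as r


@pytest.fixture(scope="session")
def small_config() -> r.SimConfig:
    return r.SimConfig(families_per_population=4, blocks_per_treatment=3, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    plants, states = r.simulate_experiment(small_config)
    return plants, states


@pytest.fixture()
def logistic_series():
    """Noise-free three-parameter logistic: A=1500, x_mid=27, scal=4."""
    t = np.arange(0.0, 61.0, 3.0)
    y = 1500.0 / (1.0 + np.exp((27.0 - t) / 4.0))
    return pd.DataFrame({"day": t, "area_mm2": y})
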