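import numpy as np
import pandas as pd
import pytest

from wiltlag.lag_correlation import AlignedDayPair
from wiltlag.synthetic_data import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def sunny_config():
    """One sunny plant-day, deterministic everywhere (no measurement noise)."""
    return ScenarioConfig(seed=11, sensor_noise_sd=0.0, stem_noise_sd=0.0, flow_noise_sd=0.0)


@pytest.fixture(scope="session")
def sunny_dataset(sunny_config):
    return generate_dataset(sunny_config, images="flows")


@pytest.fixture(scope="session")
def noisy_sunny_dataset():
    """Default study conditions: sensor and flow noise on."""
    return generate_dataset(ScenarioConfig(seed=3), images="flows")


@pytest.fixture(scope="session")
def rendered_day(sunny_config):
    """A noise-free rendered camera-window day (481 frames)."""
    return generate_dataset(sunny_config, images="frames")


def make_lagged_pair(n=476, lag=0, seed=0):
    """Aligned pair where dwilt(t) = dstem(t - lag) on white-noise dstem."""
    rng = np.random.default_rng(seed)
    ext = rng.standard_normal(n + abs(lag))
    if lag >= 0:
        dstem, dwilt = ext[lag:], ext[: n]
    else:
        dstem, dwilt = ext[: n], ext[-lag:]
    index = pd.date_range("2018-04-06 09:05", periods=n, freq="min")
    return AlignedDayPair(
        date=index[0].date(), plant_id="p", index=index,
        dstem=np.asarray(dstem[:n], float), dwilt=np.asarray(dwilt[:n], float),
    )
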