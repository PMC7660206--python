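import numpy as np
import pytest
from hypothesis import settings

from maizelai import crop, synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params() -> crop.CropParams:
    return crop.CropParams()


@pytest.fixture(scope="session")
def season_weather() -> list[crop.WeatherDay]:
    """One default synthetic season: emergence 1 June, 140 days."""
    return synthetic.gen_weather(140, seed=1)


@pytest.fixture(scope="session")
def season_sim(default_params, season_weather) -> crop.SimResult:
    return crop.simulate_season(default_params, season_weather)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_free_scene() -> synthetic.SceneParams:
    return synthetic.SceneParams(refl_noise_sd=0.0, lai_obs_noise_sd=0.0, seed=0)
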