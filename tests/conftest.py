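import numpy as np
import pytest

from maizemap.synthetic import (
    DEFAULT_PHENOLOGY,
    PhenologyParams,
    generate_sample_set,
    make_scenario,
)


@pytest.fixture
def maize_params() -> PhenologyParams:
    return DEFAULT_PHENOLOGY["maize"]


@pytest.fixture
def quiet_maize() -> PhenologyParams:
    """Maize phenology with noise and clouds switched off."""
    from dataclasses import replace

    return replace(DEFAULT_PHENOLOGY["maize"], noise_sd=0.0, cloud_prob=0.0)


@pytest.fixture(scope="session")
def small_sample_set():
    """60 samples/class from the well-separated zone-a condition (shared
    across tests that only need labeled series)."""
    return generate_sample_set(make_scenario("a", 2019, 60, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
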