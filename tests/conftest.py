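import numpy as np
import pytest

from citylur.synthetic import CityConfig, SurfaceParams, generate_city, place_sites, simulate_true_surface


@pytest.fixture(scope="session")
def city():
    """Compact city reused across tests (deterministic)."""
    return generate_city(CityConfig(extent=12_000.0, n_radial=6, n_ring=2, blocks_per_side=14), seed=7)


@pytest.fixture(scope="session")
def surface(city):
    return simulate_true_surface(city, SurfaceParams(), seed=11)


@pytest.fixture(scope="session")
def noiseless_surface(city):
    return simulate_true_surface(city, SurfaceParams(noise_sd=0.0), seed=11)


@pytest.fixture(scope="session")
def sites(city):
    return place_sites(city, n_background=40, n_traffic=20, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
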