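import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import invasibility as inv

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sites():
    """60 simulated sites (5 per river type), fixed seed."""
    specs = [
        inv.RiverTypeSpec(s.name, s.temperature, s.precipitation,
                          s.altitude, s.drainage_area, 5)
        for s in inv.default_river_types()
    ]
    return inv.simulate_sites(specs=specs, seed=42)


@pytest.fixture(scope="session")
def small_frame(small_sites):
    return inv.sites_to_frame(small_sites)


@pytest.fixture(scope="session")
def species_list():
    return [
        inv.SpeciesInfo("nns_a", "non_native"),
        inv.SpeciesInfo("nns_b", "non_native"),
        inv.SpeciesInfo("native_a", "native"),
        inv.SpeciesInfo("shad", "diadromous"),
    ]


@pytest.fixture(scope="session")
def small_table(small_sites, species_list):
    config = inv.EffectConfig(
        env_coefficients={"drainage_area": 0.5, "temperature": 0.3},
        zero_inflation_prob=0.3, seed=7)
    return inv.simulate_densities(small_sites, species_list, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
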