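import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rangecast import bioclim, synthetic_data as synth

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def landscape_small():
    return synth.make_landscape(30, 30, cell_size=10.0, seed=11)


@pytest.fixture(scope="session")
def baseline_small(landscape_small):
    return synth.make_baseline_climate(landscape_small, seed=11)


@pytest.fixture(scope="session")
def bioclim_small(baseline_small):
    return bioclim.compute_bioclim(baseline_small)


@pytest.fixture(scope="session")
def species_small(bioclim_small):
    mix = {"shrinker": 1 / 3, "shifter": 1 / 3, "stable": 1 / 3}
    return synth.make_species(6, mix, bioclim_small, seed=5)


@pytest.fixture(scope="session")
def future_bios_small(baseline_small):
    out = {}
    for scen in bioclim.SCENARIOS:
        for per in bioclim.PERIODS:
            mc = synth.make_future_climate(baseline_small, scen, per,
                                           gcm_jitter_sd=0.0, gcm="truth")
            out[(scen, per)] = bioclim.compute_bioclim(mc)
    return out


@pytest.fixture(scope="session")
def truth_small(species_small, bioclim_small, future_bios_small):
    return synth.build_truth(species_small, bioclim_small, future_bios_small)


@pytest.fixture(scope="session")
def landscape_default():
    """Full-size study landscape; the archetype calibration targets this
    geometry (fit-free, so still cheap to build)."""
    return synth.make_landscape(100, 100, cell_size=10.0, seed=3)


@pytest.fixture(scope="session")
def baseline_default(landscape_default):
    return synth.make_baseline_climate(landscape_default, seed=3)


@pytest.fixture(scope="session")
def bioclim_default(baseline_default):
    return bioclim.compute_bioclim(baseline_default)


@pytest.fixture(scope="session")
def future_bios_default(baseline_default):
    out = {}
    for scen in bioclim.SCENARIOS:
        for per in bioclim.PERIODS:
            mc = synth.make_future_climate(baseline_default, scen, per,
                                           gcm_jitter_sd=0.0, gcm="truth")
            out[(scen, per)] = bioclim.compute_bioclim(mc)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
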