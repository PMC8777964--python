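import numpy as np
import pytest

from mdisim.aerosol import SizeDistributionSpec, SourceConfig, make_population
from mdisim.airway import build_tree
from mdisim.breathing import ActuationSchedule, InhalationProfile, ScenarioConfig


@pytest.fixture(scope="session")
def tree():
    return build_tree()


@pytest.fixture(scope="session")
def default_spec():
    return SizeDistributionSpec()


@pytest.fixture(scope="session")
def small_population():
    """5k-droplet cloud shared by transport tests (session cache, read-only)."""
    return make_population(SourceConfig(n_droplets=5000, rng_seed=11))


@pytest.fixture
def control_scenario():
    return ScenarioConfig(
        profile=InhalationProfile(),
        schedule=ActuationSchedule(t_act_s=0.63),
        label="control",
        rng_seed=7,
    )


def scenario_at(t_act: float, seed: int = 7) -> ScenarioConfig:
    return ScenarioConfig(
        profile=InhalationProfile(),
        schedule=ActuationSchedule(t_act_s=t_act),
        label=f"t_act={t_act:g}",
        rng_seed=seed,
    )
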