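import dataclasses

import pytest

import forestmit as fm
from forestmit import experiment as ex

#: Seed and patch count for the shared reduced ensemble.
ENSEMBLE_SEED = 1
ENSEMBLE_PATCHES = 10


@pytest.fixture(scope="session")
def ensemble_config() -> ex.ExperimentConfig:
    return ex.ExperimentConfig(
        stand_params=fm.StandParams(n_patches=ENSEMBLE_PATCHES),
        seed=ENSEMBLE_SEED,
    )


@pytest.fixture(scope="session")
def ensemble(ensemble_config):
    """Full 3456-scenario factorial at reduced patch count.

    Returns ``(results, caches, config)``; the caches let later tests pull
    individual trajectories without re-simulating.
    """
    caches = ex.new_caches()
    results = ex.run_experiment(ensemble_config, caches)
    return results, caches, ensemble_config


@pytest.fixture
def base_scenario() -> fm.ScenarioConfig:
    return fm.ScenarioConfig(
        rcp="RCP4.5",
        disturbance_response="exponential",
        forest_age="mature",
        forest_type="NE",
        harvest_intensity=1.0,
        salvage=False,
        material_usage=1.0,
        cascade=1.0,
        decarb_2050=0.50,
    )


def make_scenario(base: fm.ScenarioConfig, **overrides) -> fm.ScenarioConfig:
    return dataclasses.replace(base, **overrides)
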