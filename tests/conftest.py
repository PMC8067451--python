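import numpy as np
import pytest

from canolux import (
    NoiseModel,
    SyntheticExperiment,
    default_species_params,
    default_treatments,
    generate_experiment,
)

#: Twice-weekly imaging grid plus the day before mizuna harvest.
IMAGING_DAYS_MIZUNA = (4, 7, 11, 14, 18, 21, 25, 26)
IMAGING_DAYS_LETTUCE = (4, 7, 11, 14, 18, 21, 25, 27)


@pytest.fixture(scope="session")
def species():
    mizuna, lettuce = default_species_params()
    return {"mizuna": mizuna, "lettuce": lettuce}


@pytest.fixture(scope="session")
def treatments():
    return default_treatments()


@pytest.fixture(scope="session")
def treatment_by_ppfd(treatments):
    return {t.ppfd: t for t in treatments}


@pytest.fixture()
def zero_noise():
    return NoiseModel().zero()


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Full default synthetic experiment (tables only), seed 2024."""
    out = tmp_path_factory.mktemp("default_dataset")
    config = SyntheticExperiment(write_images=False)
    paths = generate_experiment(config, out, seed=2024)
    return paths
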