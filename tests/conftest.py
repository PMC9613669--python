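"""Shared fixtures: small synthetic worlds and fast MCMC settings.

Worlds are deliberately small (few ages, 2 regions x 2 divisions each) so
whole-model tests run in seconds; MCMC sizes are reduced accordingly and the
tolerances in the tests account for the extra Monte-Carlo error.
"""

import numpy as np
import pytest

from mwra.config import McmcSettings, SyntheticWorldConfig
from mwra import population, synthetic


@pytest.fixture(scope="session")
def small_config() -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        n_regions=2,
        divisions_per_region=2,
        age_min=15,
        age_max=19,
        n_women_per_survey=200,
        seed=20240915,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthetic.make_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_census(small_config, small_truth):
    return synthetic.generate_census(small_config, small_truth)


@pytest.fixture(scope="session")
def small_frame(small_config, small_truth, small_census):
    counts = population.census_mwra_counts(small_census, small_config.register)
    return population.build_frame(
        counts,
        small_truth.as_migration_series(),
        small_truth.as_asfr_surface(),
        small_truth.as_survival_surface(),
        small_config.register,
    )


@pytest.fixture
def fast_mcmc() -> McmcSettings:
    return McmcSettings(n_draws=900, burn_in=300, n_chains=2, seed=7)


@pytest.fixture
def medium_mcmc() -> McmcSettings:
    return McmcSettings(n_draws=2000, burn_in=700, n_chains=2, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
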