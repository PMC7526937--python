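"""Shared fixtures: seeded synthetic environments and cohorts.

Session-scoped so the (comparatively expensive) cohort generation is done
once and reused across test modules.
"""

import numpy as np
import pytest

from upmigrate import synthetic as syn
from upmigrate.projection import observed_annual_rates


@pytest.fixture(scope="session")
def gen_config():
    return syn.default_config()


@pytest.fixture(scope="session")
def obs_env(gen_config):
    rng = np.random.default_rng(101)
    return syn.make_observed_env(gen_config, rng)


@pytest.fixture(scope="session")
def catch_series(gen_config):
    rng = np.random.default_rng(102)
    return syn.make_catch_series(gen_config, rng)


@pytest.fixture(scope="session")
def sockeye_cohort(gen_config, obs_env, catch_series):
    rng = np.random.default_rng(103)
    return syn.make_cohort(
        gen_config, obs_env, catch_series, rng, species="sockeye", n_fish=2500
    )


@pytest.fixture(scope="session")
def chinook_cohort(gen_config, obs_env, catch_series):
    rng = np.random.default_rng(104)
    return syn.make_cohort(
        gen_config, obs_env, catch_series, rng, species="chinook", n_fish=2500
    )


@pytest.fixture(scope="session")
def sockeye_rates(sockeye_cohort, catch_series):
    records, _ = sockeye_cohort
    return observed_annual_rates(records, catch_series)
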