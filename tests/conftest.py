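import datetime as dt

import numpy as np
import pytest

from stepgoals.synthetic import (
    GeneratorConfig,
    generate_hourly_steps,
    generate_profiles,
)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_participants=40,
        date_start=dt.date(2018, 1, 8),
        date_end=dt.date(2018, 1, 21),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_profiles(tiny_config):
    return generate_profiles(tiny_config)


@pytest.fixture(scope="session")
def tiny_days(tiny_config, tiny_profiles):
    return generate_hourly_steps(tiny_profiles, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
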