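import dataclasses

import pytest

from registrend.config import ScenarioConfig, with_expected_cases
from registrend.imputation import ImputationSpec, multiple_impute
from registrend.synthetic import generate_registry


@pytest.fixture(scope="session")
def small_config():
    """~6,000-case default scenario (fast unit-test scale)."""
    return with_expected_cases(ScenarioConfig(seed=101), 6000)


@pytest.fixture(scope="session")
def small_registry(small_config):
    return generate_registry(small_config)


@pytest.fixture(scope="session")
def medium_registry():
    """~15,000 cases for Monte-Carlo checks of the masking models."""
    cfg = with_expected_cases(ScenarioConfig(seed=202), 15000)
    return generate_registry(cfg)


@pytest.fixture(scope="session")
def small_stack(small_registry):
    records, _, _ = small_registry
    spec = ImputationSpec(m=3, n_cycles=2, seed=7)
    return multiple_impute(records, spec)


@pytest.fixture(scope="session")
def small_truth(small_registry):
    return small_registry[2]
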