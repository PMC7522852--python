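import numpy as np
import pytest
from hypothesis import settings

from tndcorrect import Scenario, TestPerformance, default_covariates

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture
def perf_default() -> TestPerformance:
    """The reference rapid-test performance used throughout the simulations."""
    return TestPerformance(sensitivity=0.95, specificity=0.97)


@pytest.fixture
def perf_perfect() -> TestPerformance:
    return TestPerformance(sensitivity=1.0, specificity=1.0)


@pytest.fixture
def scenario_high_ve(perf_default) -> Scenario:
    """High-effectiveness default scenario: VE 80%, case ratio 0.4, n ~ 3000."""
    return Scenario(true_ve=0.8, delta=0.4 / 0.6, performance=perf_default)


@pytest.fixture
def scenario_multivariate(scenario_high_ve) -> Scenario:
    """High-effectiveness scenario with the default age + titre confounders."""
    return scenario_high_ve.with_covariates(default_covariates())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
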