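import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mccm import (
    AnalysisConfig,
    CoupledMapParams,
    VariableRegistry,
    generate_coupled_logistic,
)


@pytest.fixture(scope="session")
def small_registry() -> VariableRegistry:
    return VariableRegistry(("steps_started", "actions_done"), ("posts", "reactions"))


@pytest.fixture(scope="session")
def logistic_series() -> np.ndarray:
    """A clean chaotic logistic-map series, T=200."""
    x, _ = generate_coupled_logistic(CoupledMapParams(T=200, seed=11))
    return x


@pytest.fixture(scope="session")
def ar1_series() -> np.ndarray:
    """A Gaussian AR(1) series with coefficient 0.6, T=500."""
    rng = np.random.default_rng(42)
    x = np.empty(500)
    x[0] = rng.normal()
    for t in range(499):
        x[t + 1] = 0.6 * x[t] + rng.normal()
    return x


@pytest.fixture()
def fast_config() -> AnalysisConfig:
    """Analysis config without the S-map diagnostic, for quicker pipelines."""
    return AnalysisConfig(run_nonlinearity=False)
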