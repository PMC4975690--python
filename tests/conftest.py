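import numpy as np
import pytest

from matevolve import EnvParams, EnvironmentProcess, ModelParams


@pytest.fixture(scope="session")
def base_model() -> ModelParams:
    """Baseline weak-selection parameter set used throughout the study."""
    return ModelParams()


@pytest.fixture(scope="session")
def step_env() -> EnvParams:
    """Sudden environmental shift (delta=10 at t=10) with AR(1) noise."""
    return EnvParams(scenario="step", delta=10.0, t_switch=10,
                     sigma_xi2=0.01, rho=0.5, tau=0.25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_env(env_params: EnvParams, n: int, seed=0) -> EnvironmentProcess:
    return EnvironmentProcess(env_params, n, seed=seed)
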