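import numpy as np
import pytest

from polyseg import FloryHugginsParams, GridSpec, GrowthSpec, ModelConfig


@pytest.fixture
def fh_params() -> FloryHugginsParams:
    """Reference Flory–Huggins parameter set of the segregation model."""
    return FloryHugginsParams(chi_p=0.2, chi_n=0.4, chi_np=1.2,
                              lambda_if=0.03, v_p=5.0, v_n=10.0)


@pytest.fixture
def small_config() -> ModelConfig:
    """Coarse, fast configuration for unit tests (N=32)."""
    return ModelConfig(grid=GridSpec(N=32, dt=0.05, sample_stride=50),
                       growth=GrowthSpec(gamma=0.0, L0=2.2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
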