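import numpy as np
import pytest

from nfdcm import ModelParams


@pytest.fixture(scope="session")
def prior_params() -> ModelParams:
    """Model at the standard prior expectations."""
    return ModelParams()


@pytest.fixture(scope="session")
def freqs() -> np.ndarray:
    """Default analysis grid: 1-60 Hz at 0.5 Hz."""
    return np.arange(1.0, 60.5, 0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
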