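import numpy as np
import pytest

from tmesim import ParameterSet


@pytest.fixture
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def literal_params() -> ParameterSet:
    """Parameters with the raw absolute-level modulation (no references)."""
    return ParameterSet(hypoxia_ref=0.0, adenosine_ref=0.0)


@pytest.fixture
def small_params() -> ParameterSet:
    """A 30x30 world with a light immune inventory for fast runs."""
    return ParameterSet(N=30, N_D=5, N_T=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
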