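import numpy as np
import pytest

from fmrisnr import DesignSpec, HRFParams, SimConfig


@pytest.fixture
def block_spec() -> DesignSpec:
    return DesignSpec("block")


@pytest.fixture
def er_spec() -> DesignSpec:
    return DesignSpec("event_related", rng_seed=11)


@pytest.fixture
def contrast_spec() -> DesignSpec:
    return DesignSpec("contrast")


@pytest.fixture
def hrf() -> HRFParams:
    return HRFParams()


@pytest.fixture
def fast_sim() -> SimConfig:
    return SimConfig(n_reps=400, rng_seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
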