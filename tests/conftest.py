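import numpy as np
import pytest

from dazzletrack import ArenaSpec, MotionParams


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture
def motion_params() -> MotionParams:
    return MotionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
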