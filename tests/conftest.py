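import numpy as np
import pytest

from brainshape import BinaryMask, PhantomSpec, make_solid_mask


@pytest.fixture(scope="session")
def ball_r20() -> BinaryMask:
    """Digital ball, radius 20 mm at 1 mm isotropic spacing."""
    return make_solid_mask(PhantomSpec(family="ball", size_mm=(20.0,)))


@pytest.fixture(scope="session")
def ball_r25() -> BinaryMask:
    """Digital ball, radius 25 mm at 1 mm isotropic spacing."""
    return make_solid_mask(PhantomSpec(family="ball", size_mm=(25.0,)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
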