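import numpy as np
import pytest

from dectlung import (
    PhantomSpec,
    RoiMask,
    default_basis,
    generate_phantom,
    render_dect,
)

SMALL_SHAPE = (48, 64, 6)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=SMALL_SHAPE, seed=7)


@pytest.fixture(scope="session")
def truth(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_truth():
    return generate_phantom(PhantomSpec(shape=SMALL_SHAPE, noise_sd_hu=(0.0, 0.0), seed=11))


@pytest.fixture(scope="session")
def noiseless_pair(noiseless_truth):
    return render_dect(noiseless_truth, default_basis(), noise_sd_hu=(0.0, 0.0))


@pytest.fixture(scope="session")
def full_mask():
    return RoiMask(np.ones(SMALL_SHAPE, dtype=bool), "all")
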