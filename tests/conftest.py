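import numpy as np
import pytest

from csmri import PhantomSpec, make_phantom, make_phantom_set


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom64():
    """One noiseless 64x64 phantom with sharp edges."""
    return make_phantom(PhantomSpec(size=(64, 64), seed=11))


@pytest.fixture(scope="session")
def phantom_stack32():
    """Twelve 32x32 phantoms for tiny training/pipeline tests."""
    return make_phantom_set(12, PhantomSpec(size=(32, 32), noise_std=0.01),
                            seed=5)
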