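import numpy as np
import pytest

from strokect.phantom import PhantomSpec, make_brain_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(20, 48, 64), fiber_count=4, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_brain_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
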