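import numpy as np
import pytest

from csvdseg import PhantomSpec, generate_patient


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(image_shape=(32, 32, 12), seed=7)


@pytest.fixture(scope="session")
def small_patient(small_spec):
    """One small phantom patient reused by read-only tests."""
    return generate_patient(small_spec, burden_level=2)
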