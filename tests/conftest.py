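import numpy as np
import pytest

from mambaseg.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_spec():
    return SyntheticSpec()


@pytest.fixture
def small_spec():
    # small volumes keep file-level tests fast; defaults otherwise
    return SyntheticSpec(volume_shape=(32, 32, 12), lesion_radius_range=(3.0, 5.0))
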