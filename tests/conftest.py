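import numpy as np
import pytest

from scalpmap import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom_1020():
    """Painted 10-20 phantom at ~2 mm mesh edge (mesh, landmarks, truth)."""
    return make_phantom(PhantomSpec(subdivisions=6, layout="10-20"))


@pytest.fixture(scope="session")
def head_coarse():
    """Unpainted coarse head surface for registration tests."""
    return make_phantom(PhantomSpec(subdivisions=5, layout="10-20", paint_markers=False))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
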