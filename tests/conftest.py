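import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_unit_dictionary(rng):
    """Random unit-norm 16 x 32 dictionary (overcomplete)."""
    D = rng.standard_normal((16, 32))
    return D / np.linalg.norm(D, axis=0)


@pytest.fixture
def orthonormal_dictionary(rng):
    """Random orthonormal 16 x 16 dictionary (square, for oracle identities)."""
    Q, _ = np.linalg.qr(rng.standard_normal((16, 16)))
    return Q
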