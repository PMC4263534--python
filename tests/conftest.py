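import numpy as np
import pytest

from atomstress import fixtures as fx


@pytest.fixture(scope="session")
def catalog():
    return fx.build_test_structures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
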