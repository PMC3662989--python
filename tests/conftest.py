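import numpy as np
import pytest

from armkin import simdata


@pytest.fixture(scope="session")
def fx():
    """Named analytic fixtures (fresh per session; generation is deterministic)."""
    return simdata.fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A uniformly random rotation (QR of a Gaussian matrix) and a
    standard-normal translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(size=3)
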