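import os

# keep linear algebra single-threaded: oversubscribed BLAS thread pools on a
# one-core runner slow the suite down by an order of magnitude
for _var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from megpli import forward_sim as fwd


@pytest.fixture(scope="session")
def head():
    return fwd.HeadModel(center=(0.0, 0.0, 0.0), radius=0.09)


@pytest.fixture(scope="session")
def sensors(head):
    """Small hemispherical cap; enough channels for beamforming tests."""
    return fwd.hemispherical_cap(head, n_sensors=40)


@pytest.fixture(scope="session")
def cap150(head):
    return fwd.hemispherical_cap(head, n_sensors=150)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
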