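import numpy as np
import pytest

from hppi.potential import calibrate
from hppi.torsion import torsion_scan


@pytest.fixture(scope="session")
def model():
    return calibrate()


@pytest.fixture(scope="session")
def tmap5(model):
    """Default-resolution torsion map, shared across tests (read-only)."""
    return torsion_scan(step=5.0, model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_rotation(rng):
    """Uniform random rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def dihedral_oracle(p1, p2, p3, p4):
    """Sign-explicit atan2 dihedral, IUPAC convention, degrees.

    Independent of the package's gemmi-backed implementation.
    """
    b0 = np.asarray(p1, float) - np.asarray(p2, float)
    b1 = np.asarray(p3, float) - np.asarray(p2, float)
    b2 = np.asarray(p4, float) - np.asarray(p3, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))
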