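import numpy as np
import pytest

from netscale import (
    SyntheticSpec,
    build_backbone,
    coarsen_ensemble,
    generate_ensemble,
)

HELIX = (-63.0, -42.0)
EXTENDED = (-120.0, 135.0)


@pytest.fixture(scope="session")
def helix10():
    """Ideal all-L decapeptide in a uniform helical conformation."""
    return build_backbone("ADSERKLVFY", [HELIX] * 10)


@pytest.fixture(scope="session")
def extended10():
    return build_backbone("ADSERKLVFY", [EXTENDED] * 10)


@pytest.fixture(scope="session")
def small_ensemble():
    """20-frame default-peptide ensemble used across modules."""
    return generate_ensemble(SyntheticSpec(n_frames=20, seed=3))


@pytest.fixture(scope="session")
def small_dataset(small_ensemble):
    X, Y = coarsen_ensemble(small_ensemble)
    return X, Y


def random_rigid_transform(rng):
    """Random proper rotation matrix and translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return Q, t
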