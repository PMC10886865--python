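import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture(scope="session")
def g1_geometry():
    import keratofem as kf
    return kf.keratoconus_grade("G1")


@pytest.fixture(scope="session")
def g1_mesh_small(g1_geometry):
    """256-element G1 mesh shared by solver/inverse tests."""
    import keratofem as kf
    return kf.generate_mesh(g1_geometry, spec=kf.MeshSpec(n_layers=2, a=2))


def random_deformation_gradients(rng, n, scale=0.04):
    """Admissible random states: moderate physiological strains, det F > 0."""
    F = np.eye(3) + scale * rng.standard_normal((n, 3, 3))
    # reject-and-replace any inverted draws
    bad = np.linalg.det(F) < 0.3
    while bad.any():
        F[bad] = np.eye(3) + scale * rng.standard_normal((int(bad.sum()), 3, 3))
        bad = np.linalg.det(F) < 0.3
    return F


def random_unit_fibers(rng, n):
    m = rng.standard_normal((n, 3))
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    n_ = rng.standard_normal((n, 3))
    n_ -= np.einsum("ij,ij->i", n_, m)[:, None] * m
    n_ /= np.linalg.norm(n_, axis=1, keepdims=True)
    return m, n_
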