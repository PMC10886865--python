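"""Constitutive model: invariants, energy, stress, tangent.

The central oracle is finite differentiation of the scalar strain energy:
the Cauchy stress must be the exact push-forward of 2 dpsi/dC, and the
material tangent the derivative of the second Piola-Kirchhoff stress, for
every zone parameter set.
"""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from keratofem.material import (FiberOverextensionError, Kinematics,
                                MaterialParams, cauchy_stress, invariants,
                                material_tangent, pk2_stress, strain_energy)
from keratofem.zones import ZoneLabel, assign_parameters

from conftest import random_deformation_gradients, random_unit_fibers

E1 = np.array([1.0, 0.0, 0.0])
E2 = np.array([0.0, 1.0, 0.0])

TABLE_ROWS = [assign_parameters(z) for z in ZoneLabel]


def kin(F, k0=5.5e6):
    return Kinematics.from_F(np.asarray(F, float), k0=k0)


# ---------------------------------------------------------------------------
# finite-difference oracles (4th-order central stencils)
# ---------------------------------------------------------------------------

def _psi(F, params, m0, n0):
    return float(strain_energy(kin(F), params, m0, n0))


def sigma_fd(F, params, m0, n0, h=1e-5):
    """Cauchy stress via sigma = J^-1 (dpsi/dF) F^T, FD in F."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            E = np.zeros((3, 3))
            E[i, j] = 1.0
            P[i, j] = (-_psi(F + 2 * h * E, params, m0, n0)
                       + 8 * _psi(F + h * E, params, m0, n0)
                       - 8 * _psi(F - h * E, params, m0, n0)
                       + _psi(F - 2 * h * E, params, m0, n0)) / (12 * h)
    return P @ F.T / np.linalg.det(F)


def pk2_of_C(C, params, m0, n0):
    L = np.linalg.cholesky(C)
    return pk2_stress(kin(L.T), params, m0, n0)


def tangent_fd(F, params, m0, n0, dC, h=1e-5):
    """Directional derivative of S along the symmetric perturbation dC."""
    C = F.T @ F
    sp = [pk2_of_C(C + s * h * dC, params, m0, n0) for s in (2, 1, -1, -2)]
    return (-sp[0] + 8 * sp[1] - 8 * sp[2] + sp[3]) / (12 * h)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_invariants_at_identity(rng):
    m0, n0 = random_unit_fibers(rng, 5)
    inv = invariants(kin(np.tile(np.eye(3), (5, 1, 1))), m0, n0)
    assert np.allclose(inv.I1, 3) and np.allclose(inv.I2, 3)
    assert np.allclose(inv.I4, 1) and np.allclose(inv.I6, 1)
    mn = np.einsum("ij,ij->i", m0, n0)
    assert np.allclose(inv.I8, mn)
    assert np.allclose(inv.I9, mn**2)


def test_invariants_isochoric_uniaxial():
    lam = 1.2
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    inv = invariants(kin(F), E1, E2)
    assert inv.I4 == pytest.approx(1.44, rel=1e-12)
    assert inv.I1 == pytest.approx(1.44 + 2 / 1.2, rel=1e-12)  # ~3.10667


def test_invariants_pure_dilation():
    for lam in (0.9, 1.3):
        inv = invariants(kin(lam * np.eye(3)), E1, E2)
        assert inv.I1 == pytest.approx(3, rel=1e-12)
        assert inv.I4 == pytest.approx(1, rel=1e-12)


def test_i9_constant_under_deformation(rng):
    m0, n0 = random_unit_fibers(rng, 1)
    F = random_deformation_gradients(rng, 4)
    inv = invariants(kin(F), m0[0], n0[0])
    assert np.allclose(inv.I9, np.dot(m0[0], n0[0]) ** 2)


def test_invariants_rejects_inverted_state():
    with pytest.raises(ValueError):
        kin(np.diag([1.0, 1.0, -1.0]))


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

def test_energy_zero_at_identity():
    for params in TABLE_ROWS:
        assert _psi(np.eye(3), params, E1, E2) == 0.0


def test_fiber_term_scalar_value():
    # lambda = 1.01 along m0, isochoric; matrix terms excluded
    lam = 1.01
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    params = MaterialParams(a1=0.0, a2=0.0, k1=50_000.0, k2=200.0,
                            active=(True, False))
    got = _psi(F, params, E1, E2)
    i4 = lam**2
    expect = 50_000.0 / 400.0 * (np.exp(200.0 * (i4 - 1) ** 2) - 1.0)
    assert got == pytest.approx(expect, rel=1e-12)
    assert got == pytest.approx(10.5196, abs=2e-4)  # frozen scalar value


def test_volumetric_term_value():
    J = 1.001
    F = J ** (1 / 3) * np.eye(3)
    params = MaterialParams(a1=0, a2=0, k1=0, k0=5.5e6, active=(False, False))
    assert _psi(F, params, E1, E2) == pytest.approx(
        0.5 * 5.5e6 * (J - 1) ** 2, rel=1e-9)  # 2.75 Pa


def test_isochoric_energy_insensitive_to_dilation(rng):
    F = random_deformation_gradients(rng, 6)
    params = assign_parameters(ZoneLabel.CENTRAL_NT_SI_STRONG)
    m0, n0 = random_unit_fibers(rng, 6)
    a = strain_energy(kin(F), params, m0, n0, parts="iso")
    b = strain_energy(kin(1.7 * F), params, m0, n0, parts="iso")
    assert np.allclose(a, b, rtol=1e-10)


def test_fiber_overextension_reported():
    F = np.diag([2.5, 2.5**-0.5, 2.5**-0.5])
    with pytest.raises(FiberOverextensionError) as err:
        _psi(F, MaterialParams(), E1, E2)
    assert err.value.i4 > 1


# ---------------------------------------------------------------------------
# Cauchy stress
# ---------------------------------------------------------------------------

def test_stress_zero_at_identity():
    for params in TABLE_ROWS:
        sig = cauchy_stress(kin(np.eye(3)), params, E1, E2)
        assert np.allclose(sig, 0, atol=1e-12)


@pytest.mark.parametrize("params", TABLE_ROWS,
                         ids=[z.name for z in ZoneLabel])
def test_stress_matches_energy_derivative(params, rng):
    """sigma == push-forward of the FD energy gradient, every zone row."""
    F = random_deformation_gradients(rng, 12)
    m0, n0 = random_unit_fibers(rng, 12)
    for k in range(12):
        sig = cauchy_stress(kin(F[k]), params, m0[k], n0[k])
        ref = sigma_fd(F[k], params, m0[k], n0[k])
        assert np.linalg.norm(sig - ref) <= 1e-6 * max(np.linalg.norm(ref), 1.0)


def test_stress_objectivity(rng):
    params = assign_parameters(ZoneLabel.TRANSITION)
    F = random_deformation_gradients(rng, 8)
    m0, n0 = random_unit_fibers(rng, 8)
    for k in range(8):
        Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        sig = cauchy_stress(kin(F[k]), params, m0[k], n0[k])
        sig_rot = cauchy_stress(kin(Q @ F[k]), params, m0[k], n0[k])
        assert np.allclose(sig_rot, Q @ sig @ Q.T, atol=1e-10 * np.abs(sig).max())


def test_stress_symmetry(rng):
    params = MaterialParams()
    F = random_deformation_gradients(rng, 10)
    sig = cauchy_stress(kin(F), params, E1, E2)
    assert np.allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-9)


def test_fiber_contribution_vanishes_at_unit_stretch():
    # I4b = 1: the (I4b - 1) factor kills the fiber stress exactly
    lam = 1.1
    F = np.diag([1.0, lam, 1 / lam])  # isochoric, m0 unstretched
    params = MaterialParams(a1=0, a2=0, k1=50_000.0, k0=1.0,
                            active=(True, False))
    sig = cauchy_stress(kin(F, k0=1.0), params, E1, E2, parts="iso")
    assert np.allclose(sig, 0, atol=1e-10)


def test_stiffening_monotone_in_k1():
    lam = 1.05
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    prev = -np.inf
    for k1 in (25_000.0, 37_500.0, 50_000.0):
        params = MaterialParams(a1=0, a2=0, k1=k1, active=(True, False))
        s_mm = cauchy_stress(kin(F), params, E1, E2, parts="iso")[0, 0]
        assert s_mm > prev
        prev = s_mm


# ---------------------------------------------------------------------------
# material tangent
# ---------------------------------------------------------------------------

def test_tangent_matches_fd(rng):
    """C_mat : dC/2 equals the FD directional derivative of S (20 states)."""
    F = random_deformation_gradients(rng, 20)
    m0, n0 = random_unit_fibers(rng, 20)
    rows = [assign_parameters(z) for z in ZoneLabel]
    for k in range(20):
        params = rows[k % len(rows)]
        Cm = material_tangent(kin(F[k]), params, m0[k], n0[k])
        dC = rng.standard_normal((3, 3))
        dC = dC + dC.T
        got = 0.5 * np.einsum("ijkl,kl->ij", Cm, dC)
        ref = tangent_fd(F[k], params, m0[k], n0[k], dC)
        assert np.linalg.norm(got - ref) <= 1e-5 * max(np.linalg.norm(ref), 1.0)


def test_tangent_minor_symmetry(rng):
    F = random_deformation_gradients(rng, 4)
    Cm = material_tangent(kin(F), MaterialParams(), E1, E2)
    assert np.allclose(Cm, np.swapaxes(Cm, -1, -2), atol=1e-6 * np.abs(Cm).max())
    assert np.allclose(Cm, np.swapaxes(np.swapaxes(Cm, -4, -2), -3, -1),
                       atol=1e-6 * np.abs(Cm).max())


def test_isotropic_small_strain_shear_modulus():
    """k1 = 0 at F = 1: tangent component 1212 equals mu = 2 (a1 + a2)."""
    params = MaterialParams(a1=40_000.0, a2=-10_000.0, k1=0.0,
                            active=(False, False))
    Cm = material_tangent(kin(np.eye(3)), params, E1, E2)
    mu = 2 * (params.a1 + params.a2)
    assert Cm[0, 1, 0, 1] == pytest.approx(mu, rel=1e-10)


@given(st.integers(0, 2**31 - 1))
def test_det_cbar_is_one(seed):
    rng = np.random.default_rng(seed)
    F = random_deformation_gradients(rng, 1)[0]
    k = kin(F)
    assert np.linalg.det(k.Cbar) == pytest.approx(1.0, rel=1e-10)
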