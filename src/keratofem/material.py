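"""Quasi-incompressible anisotropic hyperelastic corneal stroma model.

The strain energy per unit reference volume splits into a volumetric penalty
and an isochoric part evaluated on the modified right Cauchy-Green tensor
C-bar = J^(-2/3) C:

    psi = (k0/2)(J - 1)^2                                   (volumetric)
        + a1 (I1b - 3) + a2 (I2b - 3)                        (Mooney-Rivlin matrix)
        + sum_families (k1 / 2 k2) (exp[k2 (I4b - 1)^2] - 1) (Holzapfel fibers)

where I4b = m0 . C-bar m0 and I6b = n0 . C-bar n0 are the squared isochoric
fiber stretches of the two collagen families (nasal-temporal / superior-
inferior in the cornea, a single circumferential family in the limbus).
Stress and consistent tangent are derived analytically in the reference
configuration (second Piola-Kirchhoff S = 2 dpsi/dC and C_mat = 2 dS/dC) and
pushed forward to Cauchy stress; all kernels are batched over an arbitrary
number of material points.

As printed, the fiber term is symmetric in (I4b - 1) and therefore also
stiffens in compression; an optional tension-only switch restricts each
family to I4b > 1 states (the common soft-tissue convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MaterialParams",
    "Kinematics",
    "InvariantSet",
    "FiberOverextensionError",
    "invariants",
    "strain_energy",
    "pk2_stress",
    "cauchy_stress",
    "material_tangent",
    "pk2_and_tangent",
]

_I3 = np.eye(3)
# largest fiber-term exponent before reporting overextension instead of inf
_EXP_CAP = 500.0


class FiberOverextensionError(FloatingPointError):
    """Fiber exponential overflow at extreme stretch; carries the worst I4b."""

    def __init__(self, i4: float):
        super().__init__(f"fiber overextension: exp overflow at I4b = {i4:.6g}")
        self.i4 = i4


@dataclass(frozen=True)
class MaterialParams:
    """Zone material constants (SI Pa; k2 dimensionless).

    ``active`` flags the two fiber families (m0, n0); the limbus keeps a
    single circumferential family by deactivating the second.
    """

    a1: float = 40_000.0
    a2: float = -10_000.0
    k1: float = 50_000.0
    k2: float = 200.0
    k0: float = 5.5e6
    active: tuple[bool, bool] = (True, True)
    tension_only: bool = False

    def __post_init__(self):
        if self.k2 <= 0 or self.k0 <= 0:
            raise ValueError("k2 and k0 must be positive")

    def single_family(self) -> "MaterialParams":
        return replace(self, active=(True, False))


@dataclass
class Kinematics:
    """Pointwise deformation state derived from a deformation gradient."""

    F: np.ndarray
    J: np.ndarray
    Fbar: np.ndarray
    C: np.ndarray
    Cbar: np.ndarray
    bbar: np.ndarray
    p: np.ndarray  # pressure-like scalar, -k0 (J - 1), filled by stress calls

    @classmethod
    def from_F(cls, F: np.ndarray, k0: Optional[float] = None) -> "Kinematics":
        F = np.asarray(F, dtype=float)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise ValueError("non-positive det F")
        Jm13 = J ** (-1.0 / 3.0)
        Fbar = Jm13[..., None, None] * F
        C = np.swapaxes(F, -1, -2) @ F
        Cbar = Jm13[..., None, None] ** 2 * C
        bbar = Fbar @ np.swapaxes(Fbar, -1, -2)
        p = -(k0 if k0 is not None else 0.0) * (J - 1.0)
        return cls(F=F, J=J, Fbar=Fbar, C=C, Cbar=Cbar, bbar=bbar, p=np.asarray(p))


@dataclass
class InvariantSet:
    """The nine isochoric invariants; only I1b, I2b, I4b, I6b enter the energy."""

    I1: np.ndarray
    I2: np.ndarray
    I4: np.ndarray
    I5: np.ndarray
    I6: np.ndarray
    I7: np.ndarray
    I8: np.ndarray
    I9: np.ndarray


def _dots(Cbar, m0, n0):
    Cm = np.einsum("...ij,...j->...i", Cbar, m0)
    Cn = np.einsum("...ij,...j->...i", Cbar, n0)
    return Cm, Cn


def invariants(kin: Kinematics, m0: np.ndarray, n0: np.ndarray) -> InvariantSet:
    """All nine isochoric invariants of C-bar and the fiber frame (batched)."""
    Cbar = kin.Cbar
    m0 = np.asarray(m0, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    C2 = Cbar @ Cbar
    I2 = 0.5 * (I1**2 - np.trace(C2, axis1=-2, axis2=-1))
    Cm, Cn = _dots(Cbar, m0, n0)
    C2m = np.einsum("...ij,...j->...i", C2, m0)
    C2n = np.einsum("...ij,...j->...i", C2, n0)
    I4 = np.einsum("...i,...i->...", m0, Cm)
    I5 = np.einsum("...i,...i->...", m0, C2m)
    I6 = np.einsum("...i,...i->...", n0, Cn)
    I7 = np.einsum("...i,...i->...", n0, C2n)
    I8 = np.einsum("...i,...i->...", m0, Cn)
    I9 = np.einsum("...i,...i->...", m0, n0) ** 2
    return InvariantSet(I1, I2, I4, I5, I6, I7, I8, I9)


def _fiber_scalars(I4, p: MaterialParams, active):
    """f(I4), f'(I4), f''(I4) of the exponential fiber potential.

    f(I)  = (k1/2k2)(exp[k2 (I-1)^2] - 1)
    f'(I) = k1 (I-1) exp[k2 (I-1)^2]
    f''(I)= k1 (1 + 2 k2 (I-1)^2) exp[k2 (I-1)^2]
    """
    I4 = np.asarray(I4, dtype=float)
    e = I4 - 1.0
    arg = p.k2 * e**2
    if np.any(arg > _EXP_CAP):
        raise FiberOverextensionError(float(I4.ravel()[np.argmax(arg)]))
    ex = np.exp(arg)
    w = np.ones_like(I4) if active else np.zeros_like(I4)
    if p.tension_only:
        w = w * (e > 0.0)
    f = w * p.k1 / (2.0 * p.k2) * (ex - 1.0)
    f1 = w * p.k1 * e * ex
    f2 = w * p.k1 * (1.0 + 2.0 * p.k2 * e**2) * ex
    return f, f1, f2


def strain_energy(kin: Kinematics, params: MaterialParams,
                  m0: np.ndarray, n0: np.ndarray,
                  parts: str = "all") -> np.ndarray:
    """Strain energy density (Pa). ``parts`` in {"all", "iso", "vol"}."""
    inv = invariants(kin, m0, n0)
    psi_iso = params.a1 * (inv.I1 - 3.0) + params.a2 * (inv.I2 - 3.0)
    f4, _, _ = _fiber_scalars(inv.I4, params, params.active[0])
    f6, _, _ = _fiber_scalars(inv.I6, params, params.active[1])
    psi_iso = psi_iso + f4 + f6
    psi_vol = 0.5 * params.k0 * (kin.J - 1.0) ** 2
    if parts == "iso":
        return psi_iso
    if parts == "vol":
        return psi_vol
    return psi_iso + psi_vol


def _outer(a, b):
    return np.einsum("...ij,...kl->...ijkl", a, b)


def _odot(A):
    """(A (.) A)_ijkl = 1/2 (A_ik A_jl + A_il A_jk) for symmetric A."""
    return 0.5 * (np.einsum("...ik,...jl->...ijkl", A, A)
                  + np.einsum("...il,...jk->...ijkl", A, A))


def pk2_and_tangent(kin: Kinematics, params: MaterialParams,
                    m0: np.ndarray, n0: np.ndarray,
                    parts: str = "all", want_tangent: bool = True):
    """Second Piola-Kirchhoff stress and material tangent C = 2 dS/dC.

    Returns ``(S, C_mat)``; ``C_mat`` is None when ``want_tangent`` is False.
    ``parts`` selects the isochoric part, the volumetric penalty part, or
    their sum — the split the selective-reduced-integration elements need.
    """
    m0 = np.broadcast_to(np.asarray(m0, float), kin.F.shape[:-2] + (3,))
    n0 = np.broadcast_to(np.asarray(n0, float), kin.F.shape[:-2] + (3,))
    C, Cbar, J = kin.C, kin.Cbar, kin.J
    Cinv = np.linalg.inv(C)
    inv = invariants(kin, m0, n0)
    M = np.einsum("...i,...j->...ij", m0, m0)
    N = np.einsum("...i,...j->...ij", n0, n0)
    Jm23 = J ** (-2.0 / 3.0)

    _, g4, h4 = _fiber_scalars(inv.I4, params, params.active[0])
    _, g6, h6 = _fiber_scalars(inv.I6, params, params.active[1])

    S = np.zeros_like(C)
    Cm = None

    if parts in ("all", "iso"):
        # fictitious stress Sbar = 2 dpsi_iso/dCbar
        Sbar = 2.0 * (
            (params.a1 + params.a2 * inv.I1)[..., None, None] * _I3
            - params.a2 * Cbar
            + g4[..., None, None] * M
            + g6[..., None, None] * N
        )
        trSC = np.einsum("...ij,...ij->...", Sbar, C)  # Sbar : C
        S_iso = Jm23[..., None, None] * (Sbar - (trSC / 3.0)[..., None, None] * Cinv)
        S = S + S_iso
        if want_tangent:
            # fictitious elasticity  Cbar_hat = 2 dSbar/dCbar, then the
            # standard isochoric projection (deviatoric operator P).
            II = np.broadcast_to(_outer(_I3, _I3), C.shape + (3, 3))
            Isym = _odot(np.broadcast_to(_I3, C.shape))
            Chat = (4.0 * params.a2 * II
                    - 4.0 * params.a2 * Isym
                    + 4.0 * h4[..., None, None, None, None] * _outer(M, M)
                    + 4.0 * h6[..., None, None, None, None] * _outer(N, N))
            Cbb = (Jm23**2)[..., None, None, None, None] * Chat
            CC = np.einsum("...ijkl,...kl->...ij", Cbb, C)
            CCC = np.einsum("...ij,...ij->...", CC, C)
            PCP = (Cbb
                   - (1.0 / 3.0) * (_outer(Cinv, CC) + _outer(CC, Cinv))
                   + (CCC / 9.0)[..., None, None, None, None] * _outer(Cinv, Cinv))
            Ptil = _odot(Cinv) - (1.0 / 3.0) * _outer(Cinv, Cinv)
            trS = Jm23 * trSC  # (J^{-2/3} Sbar) : C
            Cm_iso = (PCP
                      + (2.0 / 3.0) * trS[..., None, None, None, None] * Ptil
                      - (2.0 / 3.0) * (_outer(Cinv, S_iso) + _outer(S_iso, Cinv)))
            Cm = Cm_iso

    if parts in ("all", "vol"):
        pt = params.k0 * (J - 1.0)  # dU/dJ
        S_vol = (J * pt)[..., None, None] * Cinv
        S = S + S_vol
        kin.p = -pt
        if want_tangent:
            Cm_vol = ((J * (pt + J * params.k0))[..., None, None, None, None]
                      * _outer(Cinv, Cinv)
                      - (2.0 * J * pt)[..., None, None, None, None] * _odot(Cinv))
            Cm = Cm_vol if Cm is None else Cm + Cm_vol

    return S, Cm


def pk2_stress(kin, params, m0, n0, parts="all"):
    S, _ = pk2_and_tangent(kin, params, m0, n0, parts=parts, want_tangent=False)
    return S


def cauchy_stress(kin: Kinematics, params: MaterialParams,
                  m0: np.ndarray, n0: np.ndarray, parts: str = "all") -> np.ndarray:
    """Cauchy stress sigma = J^-1 F S F^T (batched, symmetric)."""
    S = pk2_stress(kin, params, m0, n0, parts=parts)
    F = kin.F
    sig = np.einsum("...iI,...IJ,...jJ->...ij", F, S, F, optimize=True) / kin.J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def material_tangent(kin: Kinematics, params: MaterialParams,
                     m0: np.ndarray, n0: np.ndarray, parts: str = "all") -> np.ndarray:
    """Reference material tangent C_IJKL = 2 dS_IJ/dC_KL (= dS/dE)."""
    _, Cm = pk2_and_tangent(kin, params, m0, n0, parts=parts, want_tangent=True)
    return Cm


def spatial_tangent(kin: Kinematics, params: MaterialParams,
                    m0: np.ndarray, n0: np.ndarray, parts: str = "all") -> np.ndarray:
    """Spatial elasticity c_ijkl = J^-1 F_iI F_jJ F_kK F_lL C_IJKL."""
    Cm = material_tangent(kin, params, m0, n0, parts=parts)
    F = kin.F
    return np.einsum("...iI,...jJ,...kK,...lL,...IJKL->...ijkl",
                     F, F, F, F, Cm, optimize=True) / kin.J[..., None, None, None, None]
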