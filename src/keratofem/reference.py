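"""Verification fixtures: thick spherical shell under internal pressure.

A closed thick-walled sphere of incompressible Mooney-Rivlin material under
internal pressure has a one-dimensional semi-analytic solution: with
circumferential stretch lambda = r/R and incompressibility
r^3 - a^3 = R^3 - A^3, radial equilibrium integrates to

    P = int_{lambda_b}^{lambda_a}  W'(lambda) / (lambda^3 - 1)  d lambda,

where W(lambda) is the strain energy along the spherically symmetric path
(I1 = 2 lambda^2 + lambda^-4, I2 = lambda^4 + 2 lambda^-2).  This module
provides that quadrature (and its inversion for the inner-surface
displacement) together with a cubed-sphere hexahedral mesh of the full
shell, which serve as an independent oracle for the nonlinear solver and
its locking control.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
import scipy.sparse as sp

from .material import MaterialParams
from .mesh import HexMesh, MeshingError, hex_jacobians
from .solver import BCSpec
from .zones import FiberFrame, ZoneLabel

__all__ = ["shell_pressure", "shell_inner_displacement", "spherical_shell_mesh",
           "pinned_sphere_bc", "isotropic_params"]


def isotropic_params(a1: float = 40_000.0, a2: float = -10_000.0,
                     k0: float = 5.5e6) -> MaterialParams:
    """Matrix-only (fiberless) material for isotropic benchmarks."""
    return MaterialParams(a1=a1, a2=a2, k1=0.0, k0=k0, active=(False, False))


def _wprime(lam, a1, a2):
    return a1 * (4 * lam - 4 * lam**-5) + a2 * (4 * lam**3 - 4 * lam**-3)


def shell_pressure(u_a: float, A: float, B: float,
                   a1: float = 40_000.0, a2: float = -10_000.0) -> float:
    """Internal pressure producing inner-surface displacement ``u_a`` (m)."""
    a = A + u_a
    b = (B**3 + a**3 - A**3) ** (1.0 / 3.0)
    lam_a, lam_b = a / A, b / B
    if abs(lam_a - 1) < 1e-15:
        return 0.0

    def integrand(lam):
        d = lam**3 - 1.0
        if abs(d) < 1e-12:  # removable singularity at lambda -> 1
            return _wprime(1.0 + 1e-6, a1, a2) / ((1.0 + 1e-6) ** 3 - 1.0)
        return _wprime(lam, a1, a2) / d

    val, _ = quad(integrand, lam_b, lam_a, limit=200)
    return val


def shell_inner_displacement(P: float, A: float, B: float,
                             a1: float = 40_000.0, a2: float = -10_000.0) -> float:
    """Invert :func:`shell_pressure` for the inner radial displacement."""
    if P == 0:
        return 0.0
    # bracket on the ascending branch (MR balloons have a limit point)
    u_hi, p_hi = 1e-7 * A, shell_pressure(1e-7 * A, A, B, a1, a2)
    while p_hi < P:
        u_next = 2.0 * u_hi
        p_next = shell_pressure(u_next, A, B, a1, a2)
        if p_next <= p_hi:
            raise ValueError(f"pressure {P:.3g} Pa beyond the inflation limit point")
        u_hi, p_hi = u_next, p_next
    return brentq(lambda u: shell_pressure(u, A, B, a1, a2) - P,
                  1e-15, u_hi, xtol=1e-15, rtol=1e-13)


# ---------------------------------------------------------------------------
# Cubed-sphere hexahedral shell mesh
# ---------------------------------------------------------------------------

def _cubed_sphere_surface(n: int):
    """Equiangular cubed-sphere surface: unit nodes and outward-CCW quads."""
    xi = np.tan(np.linspace(-np.pi / 4, np.pi / 4, n + 1))
    faces = []
    for axis in range(3):
        for sign in (1.0, -1.0):
            U, V = np.meshgrid(xi, xi, indexing="ij")
            pts = np.zeros(U.shape + (3,))
            pts[..., axis] = sign
            pts[..., (axis + 1) % 3] = U
            pts[..., (axis + 2) % 3] = V
            faces.append(pts / np.linalg.norm(pts, axis=-1, keepdims=True))

    key2id: dict = {}
    nodes = []
    face_ids = []
    for pts in faces:
        ids = np.empty(pts.shape[:2], dtype=int)
        for i in range(pts.shape[0]):
            for j in range(pts.shape[1]):
                key = tuple(np.round(pts[i, j], 10))
                if key not in key2id:
                    key2id[key] = len(nodes)
                    nodes.append(pts[i, j])
                ids[i, j] = key2id[key]
        face_ids.append(ids)
    nodes = np.asarray(nodes)

    quads = []
    for ids in face_ids:
        for i in range(ids.shape[0] - 1):
            for j in range(ids.shape[1] - 1):
                q = [ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]]
                p = nodes[q]
                # orient CCW seen from outside (normal away from the center)
                nrm = np.cross(p[1] - p[0], p[3] - p[0])
                if np.dot(nrm, p.mean(axis=0)) < 0:
                    q = [q[0], q[3], q[2], q[1]]
                quads.append(q)
    return nodes, np.asarray(quads, dtype=int)


def spherical_shell_mesh(r_inner: float, r_outer: float, n_per_face: int = 6,
                         n_layers: int = 2,
                         params: MaterialParams | None = None) -> HexMesh:
    """Full thick-shell hex mesh; inner surface carries the pressure facets.

    The mesh reuses the corneal HexMesh container: all elements share one
    zone tag whose material is overridden (isotropic by default), and the
    pressure-facet normals point into the cavity.
    """
    if r_outer <= r_inner:
        raise MeshingError("outer radius must exceed inner radius")
    surf, quads = _cubed_sphere_surface(n_per_face)
    np2d = surf.shape[0]
    radii = np.linspace(r_inner, r_outer, n_layers + 1)
    nodes = np.concatenate([r * surf for r in radii], axis=0)

    hexes = np.empty((n_layers * quads.shape[0], 8), dtype=int)
    e = 0
    for layer in range(n_layers):
        lo, hi = layer * np2d, (layer + 1) * np2d
        for q in quads:
            hexes[e, :4] = q + lo
            hexes[e, 4:] = q + hi
            e += 1
    # pressure on the inner surface: outward-of-solid normals point inward
    facets = quads[:, ::-1].copy()

    E = hexes.shape[0]
    zone = np.full(E, int(ZoneLabel.CENTRAL_NT_SI_STRONG))
    fibers = FiberFrame(m0=np.tile([1.0, 0, 0], (E, 1)),
                        n0=np.tile([0.0, 1, 0], (E, 1)),
                        active=np.zeros((E, 2), dtype=bool))
    mesh = HexMesh(nodes=nodes, hexes=hexes, zone=zone,
                   octant=np.zeros(E, dtype=int), ring=np.zeros(E, dtype=int),
                   fibers=fibers, facets=facets, rim=[], n_layers=n_layers,
                   np2d=np2d, r_outer=r_outer, apex_anterior=0,
                   apex_posterior=n_layers * np2d)
    mesh.material_overrides = {int(ZoneLabel.CENTRAL_NT_SI_STRONG):
                               params or isotropic_params()}
    if np.any(hex_jacobians(mesh) <= 0):
        raise MeshingError("inverted element in spherical shell mesh")
    return mesh


def pinned_sphere_bc(mesh: HexMesh) -> BCSpec:
    """Minimal rigid-body pinning compatible with uniform radial inflation.

    Fixes in-plane translations at both +-z poles and the tangential/axial
    motion of a +x equator node: 6 constraints, all of which a purely radial
    displacement field satisfies identically.
    """
    X = mesh.nodes
    pole_p = int(np.argmax(X[:, 2]))   # exact +z pole node (n_per_face even)
    pole_m = int(np.argmin(X[:, 2]))
    equator = int(np.argmax(X[:, 0]))
    fixed = np.array([3 * pole_p, 3 * pole_p + 1,
                      3 * pole_m, 3 * pole_m + 1,
                      3 * equator + 1, 3 * equator + 2])
    ndof = 3 * mesh.n_nodes
    free = np.setdiff1d(np.arange(ndof), fixed)
    T = sp.csr_matrix((np.ones(free.size), (free, np.arange(free.size))),
                      shape=(ndof, free.size))
    return BCSpec(mode="pinned", T=T, constrained_dofs=fixed)
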