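"""Nonlinear elastostatics: assembly, follower IOP load, MPC boundary
conditions and incremental Newton solution.

The residual is assembled in a total-Lagrangian setting on the mesh passed
in (the "measured" configuration during inverse iterations).  A multiplicative
prestress deformation gradient F_pre may be supplied per Gauss point, in
which case the constitutive law is evaluated at F_total = F_inc(u) . F_pre
and the effective first Piola-Kirchhoff stress P = J_pre^-1 (F_total S) F_pre^T
is integrated against the reference gradients.

Volumetric locking of the trilinear hexes is controlled by selective reduced
integration: the deviatoric (isochoric) stress and tangent are integrated at
the 2x2x2 Gauss points, the volumetric penalty at the element centroid only
(mean-dilatation treatment).

Boundary conditions are enforced by master-slave elimination u = T q:
``embedded`` drops every rim degree of freedom; ``pivoting`` ties each rim
cross-section (one node column through the thickness) rigidly to a single
rotation angle about the local circumferential tangent through the
mid-thickness section centroid, with translations and the other two
rotations blocked.  The intraocular pressure acts as a follower load on the
posterior facets (current normals and areas), with the analytic load
stiffness in the tangent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .material import Kinematics, pk2_and_tangent
from .mesh import HexMesh, GAUSS_DSHAPE, CENTROID_DSHAPE
from .zones import ZoneLabel

__all__ = [
    "MMHG_TO_PA",
    "LoadCase",
    "BCSpec",
    "SolverConfig",
    "SolveState",
    "NewtonDivergenceError",
    "build_bc",
    "external_pressure_forces",
    "pressure_load_stiffness",
    "solve_forward",
    "identity_prestress",
]

MMHG_TO_PA = 133.322

_I3 = np.eye(3)


class NewtonDivergenceError(RuntimeError):
    def __init__(self, substep, iteration, history):
        super().__init__(
            f"Newton diverged at substep {substep}, iteration {iteration}; "
            f"residual history {['%.3e' % h for h in history]}")
        self.substep = substep
        self.iteration = iteration
        self.history = history


@dataclass(frozen=True)
class LoadCase:
    """IOP load in clinical units; converted internally to Pa."""

    iop_mmhg: float
    substeps: int = 10

    def __post_init__(self):
        if self.iop_mmhg < 0:
            raise ValueError("IOP must be >= 0")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")

    @property
    def iop_pa(self) -> float:
        return self.iop_mmhg * MMHG_TO_PA


@dataclass(frozen=True)
class SolverConfig:
    newton_tol: float = 1e-8     # relative residual
    newton_accept: float = 1e-6  # accept-on-stagnation threshold
    abs_tol: float = 1e-13       # N; residuals at roundoff level count as zero
    max_iter: int = 30
    predictor: bool = True       # extrapolate the previous substep increment


@dataclass
class BCSpec:
    """Multipoint-constraint specification as a transformation u = T q."""

    mode: str
    T: sp.csr_matrix
    constrained_dofs: np.ndarray      # dofs with no identity column
    sections: list = field(default_factory=list)  # pivoting bookkeeping
    n_master_dofs: int = 0

    def reduce(self, M):
        return self.T.T @ M @ self.T

    def expand(self, q):
        return np.asarray(self.T @ q)

    def constraint_violation(self, u: np.ndarray) -> float:
        """Distance of a displacement field from the constraint manifold
        (range of T), max norm."""
        uf = np.asarray(u).ravel()
        q = sp.linalg.lsqr(self.T, uf, atol=1e-14, btol=1e-14)[0]
        res = uf - self.T @ q
        return float(np.max(np.abs(res)))


def build_bc(mesh: HexMesh, mode: str) -> BCSpec:
    """Limbus boundary condition: 'embedded' (clamped) or 'pivoting'."""
    if mode not in ("embedded", "pivoting"):
        raise ValueError("bc mode must be 'embedded' or 'pivoting'")
    if not mesh.rim:
        raise ValueError("mesh has no rim sections")
    ndof = 3 * mesh.n_nodes
    rim_nodes = np.unique(np.concatenate(mesh.rim))
    rim_dofs = (3 * rim_nodes[:, None] + np.arange(3)).ravel()

    free_nodes = np.setdiff1d(np.arange(mesh.n_nodes), rim_nodes)
    free_dofs = (3 * free_nodes[:, None] + np.arange(3)).ravel()

    rows = [free_dofs]
    cols = [np.arange(free_dofs.size)]
    vals = [np.ones(free_dofs.size)]
    ncol = free_dofs.size
    sections = []

    if mode == "pivoting":
        for nodes_s in mesh.rim:
            X = mesh.nodes[nodes_s]
            Xc = X.mean(axis=0)  # mid-thickness section centroid
            th = np.arctan2(Xc[1], Xc[0])
            tangent = np.array([-np.sin(th), np.cos(th), 0.0])
            radial = np.array([np.cos(th), np.sin(th), 0.0])
            meridional = np.cross(tangent, radial)
            # u_i = theta * (t x (X_i - Xc)); one master rotation dof
            lever = np.cross(np.broadcast_to(tangent, X.shape), X - Xc)
            rows.append((3 * nodes_s[:, None] + np.arange(3)).ravel())
            cols.append(np.full(3 * nodes_s.size, ncol))
            vals.append(lever.ravel())
            sections.append({"nodes": nodes_s, "center": Xc, "tangent": tangent,
                             "radial": radial, "meridional": meridional,
                             "col": ncol})
            ncol += 1

    T = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ncol))
    return BCSpec(mode=mode, T=T, constrained_dofs=rim_dofs,
                  sections=sections, n_master_dofs=len(sections))


# ---------------------------------------------------------------------------
# Follower pressure load
# ---------------------------------------------------------------------------

def external_pressure_forces(mesh: HexMesh, u: np.ndarray, pressure_pa: float,
                             facets: Optional[np.ndarray] = None) -> np.ndarray:
    """Nodal follower forces of a pressure acting on the posterior facets.

    Facet normals (right-hand rule on the stored connectivity) point away
    from the solid into the pressurized chamber; the load pushes the solid in
    the -normal direction.  The exact vector area 0.5 (d1 x d2) of each
    bilinear quad is used and distributed equally to its four nodes.
    """
    if facets is None:
        facets = mesh.facets
    x = mesh.nodes + np.asarray(u).reshape(-1, 3)
    xf = x[facets]
    d1 = xf[:, 2] - xf[:, 0]
    d2 = xf[:, 3] - xf[:, 1]
    avec = 0.5 * np.cross(d1, d2)
    if pressure_pa != 0.0 and np.any(np.linalg.norm(avec, axis=1) < 1e-30):
        raise RuntimeError("degenerate (zero-area) deformed pressure facet")
    f = np.zeros_like(x)
    contrib = -(pressure_pa / 4.0) * avec
    for a in range(4):
        np.add.at(f, facets[:, a], contrib)
    return f.ravel()


def _skew(v):
    z = np.zeros(v.shape[:-1])
    return np.stack([
        np.stack([z, -v[..., 2], v[..., 1]], axis=-1),
        np.stack([v[..., 2], z, -v[..., 0]], axis=-1),
        np.stack([-v[..., 1], v[..., 0], z], axis=-1),
    ], axis=-2)


def pressure_load_stiffness(mesh: HexMesh, u: np.ndarray, pressure_pa: float):
    """COO triplets of d f_ext / d u for the follower pressure load."""
    facets = mesh.facets
    x = mesh.nodes + np.asarray(u).reshape(-1, 3)
    xf = x[facets]
    d1 = xf[:, 2] - xf[:, 0]
    d2 = xf[:, 3] - xf[:, 1]
    M1 = _skew(d1)
    M2 = _skew(d2)
    c = pressure_pa / 8.0
    # f_a = -(P/8)(d1 x d2) for every facet node a;
    # d(d1 x d2) = -skew(d2) dd1 + skew(d1) dd2, dd1 = dx2 - dx0, dd2 = dx3 - dx1
    blocks = np.stack([-c * M2, c * M1, c * M2, -c * M1], axis=1)  # (F, 4, 3, 3)
    rows, cols, vals = [], [], []
    for a in range(4):
        ra = (3 * facets[:, a][:, None] + np.arange(3))  # (F, 3)
        for ci in range(4):
            cc = (3 * facets[:, ci][:, None] + np.arange(3))
            B = blocks[:, ci]  # (F, 3, 3)
            rows.append(np.repeat(ra, 3, axis=1).ravel())
            cols.append(np.tile(cc, (1, 3)).ravel())
            vals.append(B.reshape(-1, 9).ravel())
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


# ---------------------------------------------------------------------------
# Internal forces and consistent tangent
# ---------------------------------------------------------------------------

class _ElementData:
    """Reference-configuration shape-function data, built once per solve."""

    def __init__(self, mesh: HexMesh):
        Xe = mesh.nodes[mesh.hexes]  # (E, 8, 3)
        for name, dsh in (("g", GAUSS_DSHAPE), ("c", CENTROID_DSHAPE)):
            Jm = np.einsum("gai,eaj->egij", dsh, Xe)  # dX/dxi (transposed map)
            detJ = np.linalg.det(Jm)
            if np.any(detJ <= 0):
                raise RuntimeError("non-positive reference Jacobian")
            Jinv = np.linalg.inv(Jm)
            grad = np.einsum("gak,egik->egai", dsh, Jinv)  # dN/dX (E,G,8,3)
            if name == "g":
                self.gradN, self.w = grad, detJ  # unit Gauss weights
            else:
                self.gradNc, self.wc = grad, 8.0 * detJ
        E = mesh.n_elements
        dofs = (3 * mesh.hexes[:, :, None] + np.arange(3)).reshape(E, 24)
        self.rows = np.repeat(dofs, 24, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 24)).ravel()
        self.dofs = dofs
        self.groups = [(lab, np.flatnonzero(mesh.zone == int(lab)))
                       for lab in ZoneLabel
                       if np.any(mesh.zone == int(lab))]


def identity_prestress(mesh: HexMesh) -> np.ndarray:
    """Unit prestress gradient at the 8 Gauss points + centroid, (E, 9, 3, 3)."""
    return np.broadcast_to(_I3, (mesh.n_elements, 9, 3, 3)).copy()


def _block(Fpre, grad, w, u_e, m0, n0, params, parts, want_tangent):
    """Stress/tangent contributions of one quadrature block of one zone group.

    Returns (fe, Ke, F_total): fe (Eg, 8, 3) nodal forces, Ke (Eg, 24, 24).
    """
    Finc = _I3 + np.einsum("eai,egaJ->egiJ", u_e, grad)
    F = Finc @ Fpre
    kin = Kinematics.from_F(F, k0=params.k0)
    S, Cm = pk2_and_tangent(kin, params, m0, n0, parts=parts,
                            want_tangent=want_tangent)
    Jpre = np.linalg.det(Fpre)
    wj = w / Jpre  # quadrature weight / J_pre
    # effective PK1: (F S Fpre^T), integrated with reference gradients
    P = np.einsum("egiM,egMN,egJN->egiJ", F, S, Fpre, optimize=True)
    fe = np.einsum("eg,egiJ,egaJ->eai", wj, P, grad, optimize=True)
    Ke = None
    if want_tangent:
        Sp = np.einsum("egJM,egMN,egLN->egJL", Fpre, S, Fpre, optimize=True)
        geo = np.einsum("eg,egaJ,egJL,egbL->eab", wj, grad, Sp, grad, optimize=True)
        Cm2 = np.einsum("egJM,egLN,egPMQN->egPJQL", Fpre, Fpre, Cm, optimize=True)
        A = np.einsum("egiP,egkQ,egPJQL->egiJkL", F, F, Cm2, optimize=True)
        Ke = np.einsum("eg,egaJ,egiJkL,egbL->eaibk", wj, grad, A, grad, optimize=True)
        Ke = Ke.reshape(Ke.shape[0], 24, 24)
        Kg = np.einsum("eab,ik->eaibk", geo, _I3, optimize=True).reshape(Ke.shape)
        Ke = Ke + Kg
    return fe, Ke, F


def assemble_internal(mesh: HexMesh, ed: _ElementData, u: np.ndarray,
                      Fpre: np.ndarray, want_tangent: bool = True):
    """Global internal force vector and tangent triplets (SRI elements)."""
    ndof = 3 * mesh.n_nodes
    f = np.zeros(ndof)
    vals = np.zeros(ed.rows.size) if want_tangent else None
    u_nodes = np.asarray(u).reshape(-1, 3)
    F_store = np.empty((mesh.n_elements, 9, 3, 3))

    for lab, idx in ed.groups:
        params = mesh.params_for(lab)
        u_e = u_nodes[mesh.hexes[idx]]
        m0 = mesh.fibers.m0[idx][:, None, :]
        n0 = mesh.fibers.n0[idx][:, None, :]
        fe = np.zeros((idx.size, 8, 3))
        Ke = np.zeros((idx.size, 24, 24)) if want_tangent else None
        for grad, w, gsl, parts in (
                (ed.gradN[idx], ed.w[idx], slice(0, 8), "iso"),
                (ed.gradNc[idx], ed.wc[idx], slice(8, 9), "vol")):
            fb, Kb, Ftot = _block(Fpre[idx, gsl], grad, w, u_e, m0, n0,
                                  params, parts, want_tangent)
            fe += fb
            if want_tangent:
                Ke += Kb
            F_store[idx, gsl] = Ftot
        np.add.at(f, (3 * mesh.hexes[idx][:, :, None] + np.arange(3)).ravel(),
                  fe.ravel())
        if want_tangent:
            flat = np.zeros((mesh.n_elements, 576))
            flat[idx] = Ke.reshape(idx.size, 576)
            vals += flat.ravel()
    return f, vals, F_store


# ---------------------------------------------------------------------------
# Incremental Newton solve
# ---------------------------------------------------------------------------

@dataclass
class SolveState:
    """Converged forward solution."""

    mesh: HexMesh
    u: np.ndarray                 # (N, 3) nodal displacements
    F_gp: np.ndarray              # (E, 9, 3, 3) total F (8 GP + centroid)
    Fpre: np.ndarray              # prestress gradient used
    reactions: np.ndarray         # residual on constrained dofs, (ndof,)
    bc: BCSpec
    load: LoadCase
    log: list                     # per-substep residual histories
    converged: bool = True

    @property
    def deformed(self) -> np.ndarray:
        return self.mesh.nodes + self.u

    def incremental_F(self) -> np.ndarray:
        """F_inc = F_total F_pre^-1 per Gauss point."""
        return self.F_gp @ np.linalg.inv(self.Fpre)


def solve_forward(mesh: HexMesh, bc: BCSpec, load: LoadCase,
                  Fpre: Optional[np.ndarray] = None,
                  config: SolverConfig = SolverConfig(),
                  ramp_prestress: bool = True) -> SolveState:
    """Incremental-load Newton solution of the pressurized cornea.

    The pressure (and, if requested, the deviation of F_pre from identity) is
    ramped in ``load.substeps`` equal increments; each substep runs a full
    Newton iteration on the MPC-reduced system with the follower-load
    stiffness in the tangent.
    """
    ed = _ElementData(mesh)
    ndof = 3 * mesh.n_nodes
    if Fpre is None:
        Fpre = identity_prestress(mesh)
    u = np.zeros(ndof)
    T = bc.T
    log = []
    F_gp = np.broadcast_to(_I3, (mesh.n_elements, 9, 3, 3)).copy()
    f_int = np.zeros(ndof)
    f_ext = np.zeros(ndof)

    pre_dev = Fpre - _I3
    has_pre = np.max(np.abs(pre_dev)) > 0
    du_prev = np.zeros(ndof)

    for k in range(1, load.substeps + 1):
        lam = k / load.substeps
        Pk = lam * load.iop_pa
        Fk = _I3 + lam * pre_dev if (has_pre and ramp_prestress) else Fpre
        hist = []
        u_start = u.copy()
        if config.predictor and k > 1:
            try:  # extrapolated initial guess; fall back on element inversion
                f_int, Kv, F_gp = assemble_internal(mesh, ed, u + du_prev, Fk)
                u = u + du_prev
            except ValueError:
                f_int, Kv, F_gp = assemble_internal(mesh, ed, u, Fk)
        else:
            f_int, Kv, F_gp = assemble_internal(mesh, ed, u, Fk)
        for it in range(config.max_iter + 1):
            f_ext = external_pressure_forces(mesh, u, Pk)
            R = f_int - f_ext
            Rr = T.T @ R
            nR = np.linalg.norm(Rr)
            if it == 0:
                scale = max(np.linalg.norm(T.T @ f_ext), nR, 1e-30)
            res = nR / scale
            hist.append(res)
            if res < config.newton_tol or nR < config.abs_tol:
                break
            if it == config.max_iter:
                if res < config.newton_accept:
                    break
                raise NewtonDivergenceError(k, it, hist)
            K = sp.coo_matrix((Kv, (ed.rows, ed.cols)), shape=(ndof, ndof)).tocsr()
            lr, lc, lv = pressure_load_stiffness(mesh, u, Pk)
            K = K - sp.coo_matrix((lv, (lr, lc)), shape=(ndof, ndof)).tocsr()
            Kr = (T.T @ K @ T).tocsc()
            dq = spsolve(Kr, -Rr)
            # step halving guards against element inversion mid-update
            step = 1.0
            for _ in range(6):
                try:
                    u_try = u + step * (T @ dq)
                    f_int, Kv, F_gp = assemble_internal(mesh, ed, u_try, Fk)
                    break
                except ValueError:
                    step *= 0.5
            else:
                raise NewtonDivergenceError(k, it, hist)
            u = u_try
        du_prev = u - u_start
        log.append(hist)

    reactions = np.zeros(ndof)
    R = f_int - f_ext
    reactions[bc.constrained_dofs] = R[bc.constrained_dofs]
    return SolveState(mesh=mesh, u=u.reshape(-1, 3), F_gp=F_gp, Fpre=Fpre,
                      reactions=reactions, bc=bc, load=load, log=log)
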