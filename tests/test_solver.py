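"""Nonlinear solver: pressure loads, MPCs, equilibrium, invariances."""
from types import SimpleNamespace

import numpy as np
import pytest

import keratofem.geometry as gg
import keratofem as kf
from keratofem.mesh import MeshSpec, generate_mesh
from keratofem.reference import isotropic_params, spherical_shell_mesh, \
    pinned_sphere_bc
from keratofem.solver import (LoadCase, MMHG_TO_PA, NewtonDivergenceError,
                              SolverConfig, build_bc,
                              external_pressure_forces,
                              pressure_load_stiffness, solve_forward)
from keratofem.zones import ZoneLabel


@pytest.fixture(scope="module")
def iso_cap_mesh():
    g = kf.make_cornea(gg.default_anterior(), gg.default_posterior())
    m = generate_mesh(g, spec=MeshSpec(n_layers=2, a=2))
    m.material_overrides = {int(z): isotropic_params() for z in ZoneLabel}
    return m


@pytest.fixture(scope="module")
def small_mesh(g1_geometry):
    return generate_mesh(g1_geometry, spec=MeshSpec(n_layers=1, a=2))


def test_mmhg_conversion():
    assert LoadCase(15.0).iop_pa == pytest.approx(15 * 133.322)
    with pytest.raises(ValueError):
        LoadCase(-1.0)
    with pytest.raises(ValueError):
        LoadCase(10.0, substeps=0)


def test_zero_iop_gives_exactly_zero_displacement(small_mesh):
    bc = build_bc(small_mesh, "embedded")
    st = solve_forward(small_mesh, bc, LoadCase(0.0))
    assert np.all(st.u == 0.0)
    assert st.converged


def test_flat_facet_total_force():
    nodes = np.array([[0, 0, 0], [2.0, 0, 0], [2.0, 3.0, 0], [0, 3.0, 0.0]])
    mesh = SimpleNamespace(nodes=nodes, facets=np.array([[0, 1, 2, 3]]))
    P = 123.0
    f = external_pressure_forces(mesh, np.zeros(12), P).reshape(-1, 3)
    assert np.allclose(f.sum(axis=0), [0, 0, -P * 6.0])  # P*A against +z normal
    assert np.allclose(f, f[0])  # equal split over the four nodes


def test_pressure_force_linear_in_load():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.2], [0, 1, 0.1]])
    mesh = SimpleNamespace(nodes=nodes, facets=np.array([[0, 1, 2, 3]]))
    f1 = external_pressure_forces(mesh, np.zeros(12), 10.0)
    f2 = external_pressure_forces(mesh, np.zeros(12), 20.0)
    assert np.allclose(f2, 2 * f1)


def test_closed_surface_zero_net_force():
    mesh = spherical_shell_mesh(6.5e-3, 7.0e-3, n_per_face=4, n_layers=1)
    f = external_pressure_forces(mesh, np.zeros(3 * mesh.n_nodes), 2000.0)
    net = f.reshape(-1, 3).sum(axis=0)
    assert np.linalg.norm(net) < 1e-12 * 2000.0 * (6.5e-3) ** 2


def test_load_stiffness_matches_finite_differences(rng):
    nodes = rng.normal(size=(4, 3))
    mesh = SimpleNamespace(nodes=nodes, facets=np.array([[0, 1, 2, 3]]))
    P = 57.0
    u0 = 0.01 * rng.normal(size=12)
    r, c, v = pressure_load_stiffness(mesh, u0, P)
    K = np.zeros((12, 12))
    for ri, ci, vi in zip(r, c, v):
        K[ri, ci] += vi
    h = 1e-7
    for j in range(12):
        du = np.zeros(12)
        du[j] = h
        fd = (external_pressure_forces(mesh, u0 + du, P)
              - external_pressure_forces(mesh, u0 - du, P)) / (2 * h)
        assert np.allclose(K[:, j], fd, atol=1e-6 * max(1.0, np.abs(fd).max()))


def test_embedded_bc_constrains_all_rim_dofs(small_mesh):
    bc = build_bc(small_mesh, "embedded")
    n_rim = np.unique(np.concatenate(small_mesh.rim)).size
    assert bc.constrained_dofs.size == 3 * n_rim
    assert bc.T.shape == (3 * small_mesh.n_nodes,
                          3 * (small_mesh.n_nodes - n_rim))
    with pytest.raises(ValueError):
        build_bc(small_mesh, "roller")


def test_pivoting_rigid_rotation_in_constraint_nullspace(small_mesh):
    bc = build_bc(small_mesh, "pivoting")
    u = np.zeros((small_mesh.n_nodes, 3))
    sec = bc.sections[3]
    theta = 1e-3
    lever = np.cross(sec["tangent"], small_mesh.nodes[sec["nodes"]] - sec["center"])
    u[sec["nodes"]] = theta * lever
    assert bc.constraint_violation(u) < 1e-12 * theta + 1e-18


def test_pivoting_blocks_radial_translation(small_mesh):
    bc = build_bc(small_mesh, "pivoting")
    sec = bc.sections[0]
    u = np.zeros((small_mesh.n_nodes, 3))
    u[sec["nodes"]] = 1e-4 * sec["radial"]  # diameter change: forbidden
    assert bc.constraint_violation(u) > 1e-5


def test_equilibrium_and_reactions(small_mesh):
    bc = build_bc(small_mesh, "embedded")
    load = LoadCase(15.0, substeps=5)
    st = solve_forward(small_mesh, bc, load)
    from keratofem.solver import _ElementData, assemble_internal
    ed = _ElementData(small_mesh)
    f_int, _, _ = assemble_internal(small_mesh, ed, st.u.ravel(), st.Fpre,
                                    want_tangent=False)
    f_ext = external_pressure_forces(small_mesh, st.u, load.iop_pa)
    R = f_int - f_ext
    free = np.setdiff1d(np.arange(R.size), bc.constrained_dofs)
    rel = np.linalg.norm(R[free]) / np.linalg.norm(f_ext)
    assert rel < 1e-8
    # reactions appear only on constrained dofs and balance the load
    assert np.all(st.reactions[free] == 0)
    assert np.allclose(st.reactions[bc.constrained_dofs],
                       R[bc.constrained_dofs])


def test_small_pressure_linearity(small_mesh):
    bc = build_bc(small_mesh, "embedded")
    u1 = solve_forward(small_mesh, bc, LoadCase(0.05, substeps=1)).u
    u2 = solve_forward(small_mesh, bc, LoadCase(0.10, substeps=1)).u
    assert np.linalg.norm(u2 - 2 * u1) / np.linalg.norm(u2) < 0.01


def test_substep_insensitivity(small_mesh):
    """Elastostatics is path independent: 10 vs 20 substeps agree."""
    bc = build_bc(small_mesh, "embedded")
    cfg = SolverConfig(newton_tol=1e-12, newton_accept=1e-10)
    u10 = solve_forward(small_mesh, bc, LoadCase(15.0, substeps=10), config=cfg).u
    u20 = solve_forward(small_mesh, bc, LoadCase(15.0, substeps=20), config=cfg).u
    assert np.linalg.norm(u20 - u10) / np.linalg.norm(u10) < 1e-6


def test_frame_invariance(g1_geometry):
    """Rotating mesh, fibers and load rotates the solution field."""
    mesh = generate_mesh(g1_geometry, spec=MeshSpec(n_layers=1, a=2))
    cfg = SolverConfig(newton_tol=1e-12, newton_accept=1e-10)
    load = LoadCase(15.0, substeps=2)
    st = solve_forward(mesh, build_bc(mesh, "embedded"), load, config=cfg)

    ang = 0.37
    Q = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    Q = Q @ np.array([[1, 0, 0], [0, np.cos(0.21), -np.sin(0.21)],
                      [0, np.sin(0.21), np.cos(0.21)]])
    rot = mesh.with_coords(mesh.nodes @ Q.T)
    from keratofem.zones import FiberFrame
    rot.fibers = FiberFrame(m0=mesh.fibers.m0 @ Q.T, n0=mesh.fibers.n0 @ Q.T,
                            active=mesh.fibers.active)
    st_rot = solve_forward(rot, build_bc(rot, "embedded"), load, config=cfg)
    err = np.abs(st_rot.u - st.u @ Q.T).max() / np.abs(st.u).max()
    assert err < 1e-8


def test_pivoting_softer_than_embedded(iso_cap_mesh):
    """Pivoting admits every embedded state plus rim rotations, so the
    pressure does at least as much work on the pivoting solution."""
    load = LoadCase(15.0)
    W = {}
    for mode in ("embedded", "pivoting"):
        st = solve_forward(iso_cap_mesh, build_bc(iso_cap_mesh, mode), load)
        f = external_pressure_forces(iso_cap_mesh, st.u, load.iop_pa)
        W[mode] = float(f @ st.u.ravel())
    assert W["pivoting"] >= W["embedded"]


def test_newton_divergence_reported(iso_cap_mesh):
    bc = build_bc(iso_cap_mesh, "embedded")
    with pytest.raises(NewtonDivergenceError) as err:
        solve_forward(iso_cap_mesh, bc, LoadCase(4000.0, substeps=1),
                      config=SolverConfig(max_iter=4, newton_accept=1e-12))
    assert err.value.substep == 1
    assert len(err.value.history) >= 1


def test_mesh_convergence_of_apex_displacement(g1_geometry):
    """Apex displacement changes < 2% under uniform x2 refinement."""
    load = LoadCase(15.0)
    apex = []
    for spec in (MeshSpec(n_layers=2, a=2),
                 MeshSpec(n_layers=4, a=4, radial_factor=2)):
        m = generate_mesh(g1_geometry, spec=spec)
        st = solve_forward(m, build_bc(m, "embedded"), load)
        apex.append(np.linalg.norm(st.u[m.apex_anterior]))
    assert abs(apex[1] - apex[0]) / apex[1] < 0.02
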