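"""Derived fields, zone-wise summaries and VTK export.

Von Mises stress is the usual deviatoric intensity sqrt(3/2 dev(s):dev(s)).
"Von Mises" equivalent strain follows the common FE-postprocessor
convention: the same deviatoric intensity applied to the logarithmic
(Hencky) strain tensor scaled by 1/(1 + nu_eff) with effective Poisson
ratio 0.5, so that a uniaxial incompressible strain state diag(e, -e/2,
-e/2) reports e.

The VTK writer emits legacy-ASCII unstructured grids (hexahedra) carrying
displacement, stress, strain and zone arrays; a matching reader round-trips
them for testing and external visualization.
"""
from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

from .material import Kinematics, cauchy_stress
from .mesh import HexMesh
from .solver import SolveState
from .zones import ZoneLabel

__all__ = ["von_mises", "equivalent_strain", "log_strain", "FieldReport",
           "field_report", "zone_summary", "export_vtk", "read_vtk",
           "summary_json"]

NU_EFF = 0.5


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises stress of symmetric 3x3 tensors (batched)."""
    sigma = np.asarray(sigma, dtype=float)
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dev = sigma - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def log_strain(F: np.ndarray) -> np.ndarray:
    """Logarithmic (Hencky) strain tensor from deformation gradients."""
    F = np.asarray(F, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    lam2, Q = np.linalg.eigh(C)
    loge = 0.5 * np.log(lam2)
    return np.einsum("...ik,...k,...jk->...ij", Q, loge, Q)


def equivalent_strain(strain: np.ndarray, nu_eff: float = NU_EFF) -> np.ndarray:
    """Von Mises-type equivalent of a (log) strain tensor."""
    strain = np.asarray(strain, dtype=float)
    tr = np.trace(strain, axis1=-2, axis2=-1)
    dev = strain - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev)) / (1.0 + nu_eff)


@dataclass
class FieldReport:
    """Field arrays of a solved state plus their extrema locations."""

    total_displacement: np.ndarray   # (N,) m
    vm_stress_gp: np.ndarray         # (E, 8) Pa
    eq_strain_gp: np.ndarray         # (E, 8) m/m
    vm_stress_elem: np.ndarray       # (E,) Gauss-point mean
    eq_strain_elem: np.ndarray       # (E,)
    max_displacement_node: int
    max_vm_stress_element: int
    max_eq_strain_element: int


def field_report(state: SolveState) -> FieldReport:
    """Evaluate displacement magnitude, von Mises stress and equivalent
    strain at the Gauss points of a converged solve."""
    mesh = state.mesh
    disp = np.linalg.norm(state.u, axis=1)
    E = mesh.n_elements
    vm = np.zeros((E, 8))
    eq = np.zeros((E, 8))
    for lab in ZoneLabel:
        idx = np.flatnonzero(mesh.zone == int(lab))
        if idx.size == 0:
            continue
        params = mesh.params_for(lab)
        F = state.F_gp[idx, :8]
        kin = Kinematics.from_F(F, k0=params.k0)
        m0 = mesh.fibers.m0[idx][:, None, :]
        n0 = mesh.fibers.n0[idx][:, None, :]
        vm[idx] = von_mises(cauchy_stress(kin, params, m0, n0))
        eq[idx] = equivalent_strain(log_strain(F))
    return FieldReport(
        total_displacement=disp,
        vm_stress_gp=vm, eq_strain_gp=eq,
        vm_stress_elem=vm.mean(axis=1), eq_strain_elem=eq.mean(axis=1),
        max_displacement_node=int(np.argmax(disp)),
        max_vm_stress_element=int(np.argmax(vm.max(axis=1))),
        max_eq_strain_element=int(np.argmax(eq.max(axis=1))),
    )


def zone_summary(report: FieldReport, mesh: HexMesh) -> pd.DataFrame:
    """Per-zone extrema and means of the derived fields."""
    rows = []
    for lab in ZoneLabel:
        idx = np.flatnonzero(mesh.zone == int(lab))
        if idx.size == 0:
            continue
        vm = report.vm_stress_gp[idx]
        eq = report.eq_strain_gp[idx]
        rows.append({
            "zone": lab.name,
            "n_elements": int(idx.size),
            "vm_stress_max_pa": float(vm.max()),
            "vm_stress_mean_pa": float(vm.mean()),
            "vm_stress_argmax_element": int(idx[np.argmax(vm.max(axis=1))]),
            "eq_strain_max": float(eq.max()),
            "eq_strain_mean": float(eq.mean()),
            "eq_strain_argmax_element": int(idx[np.argmax(eq.max(axis=1))]),
        })
    return pd.DataFrame(rows)


def ring_summary(report: FieldReport, mesh: HexMesh) -> pd.DataFrame:
    rows = []
    for ring in np.unique(mesh.ring):
        idx = np.flatnonzero(mesh.ring == ring)
        rows.append({
            "ring": int(ring),
            "n_elements": int(idx.size),
            "vm_stress_max_pa": float(report.vm_stress_gp[idx].max()),
            "eq_strain_max": float(report.eq_strain_gp[idx].max()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Legacy-ASCII VTK unstructured grid I/O
# ---------------------------------------------------------------------------

def export_vtk(path, mesh: HexMesh, point_data: dict | None = None,
               cell_data: dict | None = None, title: str = "keratofem") -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    N, E = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {N} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {E} {E * 9}\n")
        np.savetxt(fh, np.hstack([np.full((E, 1), 8), mesh.hexes]), fmt="%d")
        fh.write(f"CELL_TYPES {E}\n")
        np.savetxt(fh, np.full(E, 12, dtype=int), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {N}\n")
            _write_arrays(fh, point_data, N)
        if cell_data:
            fh.write(f"CELL_DATA {E}\n")
            _write_arrays(fh, cell_data, E)


def _write_arrays(fh, arrays: dict, n: int) -> None:
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.shape[0] != n:
            raise ValueError(f"array {name!r} has wrong length")
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.17g")
        elif arr.ndim == 1:
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"SCALARS {name} {kind}\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%d" if kind == "int" else "%.17g")
        else:
            raise ValueError(f"unsupported array shape {arr.shape} for {name!r}")


def read_vtk(path):
    """Minimal reader for the files written by :func:`export_vtk`.

    Returns (points, cells, point_data, cell_data).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    points = cells = None
    point_data: dict = {}
    cell_data: dict = {}
    target = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "POINTS":
            n = int(tok[1])
            points = np.array([lines[i + 1 + j].split() for j in range(n)], dtype=float)
            i += n + 1
        elif key == "CELLS":
            n = int(tok[1])
            raw = np.array([lines[i + 1 + j].split() for j in range(n)], dtype=int)
            cells = raw[:, 1:]
            i += n + 1
        elif key == "CELL_TYPES":
            i += int(tok[1]) + 1
        elif key == "POINT_DATA":
            target = point_data
            i += 1
        elif key == "CELL_DATA":
            target = cell_data
            i += 1
        elif key == "VECTORS":
            n = points.shape[0] if target is point_data else cells.shape[0]
            target[tok[1]] = np.array(
                [lines[i + 1 + j].split() for j in range(n)], dtype=float)
            i += n + 1
        elif key == "SCALARS":
            n = points.shape[0] if target is point_data else cells.shape[0]
            dtype = int if tok[2] == "int" else float
            target[tok[1]] = np.array(lines[i + 2:i + 2 + n], dtype=dtype)
            i += n + 2
        else:
            i += 1
    return points, cells, point_data, cell_data


def export_state_vtk(path, state: SolveState, report: FieldReport | None = None):
    """Convenience export of a solved state with its standard field set."""
    report = report or field_report(state)
    mesh = state.mesh
    export_vtk(
        path, mesh,
        point_data={"displacement": state.u,
                    "total_displacement": report.total_displacement},
        cell_data={"zone_label": mesh.zone.astype(int),
                   "octant": mesh.octant.astype(int),
                   "ring": mesh.ring.astype(int),
                   "von_mises_stress": report.vm_stress_elem,
                   "equivalent_strain": report.eq_strain_elem},
    )


def summary_json(report: FieldReport, mesh: HexMesh, extra: dict | None = None) -> str:
    """Deterministic machine-readable run summary (byte-stable JSON).

    Fields are reported in SI and, for comparability with clinical tables,
    displacements additionally in micrometers.
    """
    zs = zone_summary(report, mesh)
    payload = {
        "n_nodes": int(mesh.n_nodes),
        "n_elements": int(mesh.n_elements),
        "max_total_displacement_m": float(report.total_displacement.max()),
        "max_total_displacement_um": float(report.total_displacement.max() * 1e6),
        "max_von_mises_stress_pa": float(report.vm_stress_gp.max()),
        "max_equivalent_strain": float(report.eq_strain_gp.max()),
        "zones": zs.to_dict(orient="records"),
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, sort_keys=True, indent=1)
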