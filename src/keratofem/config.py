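"""Run configuration: one YAML file drives the whole pipeline.

Keys (all optional, with the package defaults):

.. code-block:: yaml

    geometry:
      grade: G1              # synthetic keratoconus fixture, or explicit:
      anterior_radius_m: 7.8e-3
      posterior_radius_m: 6.5e-3
      central_thickness_m: 5.5e-4
      cone: {amplitude_m: 2.0e-5, r0_m: 1.5e-3, theta0_deg: -60.0,
             sigma_m: 1.5e-3, thinning: 0.1}
    segmentation:
      ring_diameters_mm: [2, 4, 6, 8, 10, 11]
      sector_half_width_deg: 22.5
      limbus_outer_radius_mm: 6.25
    mesh: {n_layers: 4, a: 2, nt: 1}
    load: {iop_mmhg: 15.0, substeps: 10}
    solver: {newton_tol: 1.0e-9, max_iter: 30}
    bc: {mode: embedded}
    inverse: {tol: 1.0e-9, max_iter: 50, relaxation: 1.0}
    material:
      k0: 5.5e6
      zones: {TRANSITION: {k1: 37500.0}}   # per-zone overrides, Table rows
"""
from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Optional

import numpy as np
import yaml

from .geometry import (BiconicParams, ConePerturbation, CornealGeometry,
                       keratoconus_grade, make_cornea)
from .inverse import InverseConfig
from .material import MaterialParams
from .mesh import MeshSpec
from .solver import LoadCase, SolverConfig
from .zones import SegmentationSpec, ZoneLabel

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)

    def geometry(self) -> CornealGeometry:
        g = self.raw.get("geometry", {}) or {}
        if "grade" in g:
            return keratoconus_grade(g["grade"])
        cct = float(g.get("central_thickness_m", 5.5e-4))
        ant = BiconicParams(Rx=float(g.get("anterior_radius_m", 7.8e-3)),
                            Ry=float(g.get("anterior_radius_m", 7.8e-3)),
                            role="anterior")
        post = BiconicParams(Rx=float(g.get("posterior_radius_m", 6.5e-3)),
                             Ry=float(g.get("posterior_radius_m", 6.5e-3)),
                             role="posterior", offset=cct)
        cone = None
        if "cone" in g and g["cone"]:
            c = g["cone"]
            cone = ConePerturbation(
                amplitude=float(c.get("amplitude_m", 0.0)),
                r0=float(c.get("r0_m", 1.5e-3)),
                theta0=np.deg2rad(float(c.get("theta0_deg", 0.0))),
                sigma=float(c.get("sigma_m", 1.5e-3)),
                thinning=float(c.get("thinning", 0.0)))
        seg = self.segmentation()
        return make_cornea(ant, post, cone=cone, r_max=seg.r_limbus_outer)

    def segmentation(self) -> SegmentationSpec:
        s = self.raw.get("segmentation", {}) or {}
        return SegmentationSpec(
            ring_diameters_mm=tuple(s.get("ring_diameters_mm", (2, 4, 6, 8, 10, 11))),
            sector_half_width_deg=float(s.get("sector_half_width_deg", 22.5)),
            r_limbus_outer=float(s.get("limbus_outer_radius_mm", 6.25)) * 1e-3)

    def mesh_spec(self) -> MeshSpec:
        from .mesh import default_study_spec
        m = self.raw.get("mesh", {}) or {}
        seg = self.segmentation()
        n_bands = len(seg.ring_diameters_mm)
        rd = m.get("ring_divisions")
        if rd is None and n_bands == 6:
            base = default_study_spec(n_layers=int(m.get("n_layers", 4)),
                                      a=int(m.get("a", 2)))
            return MeshSpec(n_layers=base.n_layers, a=base.a,
                            nt=int(m.get("nt", 1)),
                            ring_divisions=base.ring_divisions)
        return MeshSpec(n_layers=int(m.get("n_layers", 4)),
                        a=int(m.get("a", 2)), nt=int(m.get("nt", 1)),
                        ring_divisions=tuple(rd) if rd else None)

    def load_case(self, iop_mmhg: Optional[float] = None) -> LoadCase:
        ld = self.raw.get("load", {}) or {}
        return LoadCase(iop_mmhg=float(iop_mmhg if iop_mmhg is not None
                                       else ld.get("iop_mmhg", 15.0)),
                        substeps=int(ld.get("substeps", 10)))

    def solver_config(self) -> SolverConfig:
        s = self.raw.get("solver", {}) or {}
        return SolverConfig(newton_tol=float(s.get("newton_tol", 1e-9)),
                            max_iter=int(s.get("max_iter", 30)))

    def bc_mode(self, override: Optional[str] = None) -> str:
        return override or (self.raw.get("bc", {}) or {}).get("mode", "embedded")

    def inverse_config(self, tol: Optional[float] = None) -> InverseConfig:
        iv = self.raw.get("inverse", {}) or {}
        return InverseConfig(tol=float(tol if tol is not None else iv.get("tol", 1e-9)),
                             max_iter=int(iv.get("max_iter", 50)),
                             relaxation=float(iv.get("relaxation", 1.0)))

    def material_overrides(self) -> Optional[dict]:
        mat = self.raw.get("material", {}) or {}
        zones = mat.get("zones", {}) or {}
        k0 = mat.get("k0")
        if not zones and k0 is None:
            return None
        from .zones import assign_parameters
        out = {}
        for lab in ZoneLabel:
            base = assign_parameters(lab)
            kw = {k: float(v) for k, v in zones.get(lab.name, {}).items()}
            if k0 is not None:
                kw.setdefault("k0", float(k0))
            if kw:
                out[int(lab)] = replace(base, **kw)
        return out or None


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig({})
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh) or {})
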