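"""Structured, zone-conforming hexahedral meshing of the corneal solid.

The planform is meshed with a butterfly/O-grid layout: a central square core
(rotated 22.5 deg so that both its corners and all sector-boundary meridians
are mesh lines), a transition band morphing the square onto the first ring
circle, and structured annular rings whose boundaries coincide with the
segmentation circles.  The solid is built by layering the planform between
the anterior and posterior surfaces (equal spacing through the thickness);
the outermost node columns are tilted onto the corneo-scleral cut cone.

With L layers, core size ns x ns (ns = 2a), nt transition divisions, a
angular divisions per octant and radial divisions r_i per ring band, the
element count is the closed form  L * (ns^2 + 4 ns nt + 8 a sum_i r_i).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import CornealGeometry
from .zones import SegmentationSpec, classify_point, fiber_frame, FiberFrame

__all__ = ["MeshSpec", "HexMesh", "MeshingError", "generate_mesh",
           "default_study_spec", "posterior_facets", "rim_sections",
           "hex_jacobians", "hex_volumes"]

# 2x2x2 Gauss points / weights on [-1,1]^3 and the centroid point
_G = 1.0 / np.sqrt(3.0)
GAUSS_PTS = np.array([[sx * _G, sy * _G, sz * _G]
                      for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
GAUSS_WTS = np.ones(8)
CENTROID_PT = np.zeros((1, 3))

# trilinear hex: corner signs in VTK ordering (bottom CCW, then top CCW)
_CORNERS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def default_study_spec(n_layers: int = 4, a: int = 2) -> "MeshSpec":
    """Canonical corneal study resolution: 4 through-thickness layers and a
    doubly-divided limbus band (the clamped-boundary layer lives there)."""
    return MeshSpec(n_layers=n_layers, a=a, ring_divisions=(1, 1, 1, 1, 1, 2))


class MeshingError(RuntimeError):
    def __init__(self, msg, element: Optional[int] = None):
        super().__init__(msg)
        self.element = element


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/dxi of the 8 trilinear shape functions at points xi (npts, 3)."""
    xi = np.atleast_2d(xi)
    g = np.empty((xi.shape[0], 8, 3))
    for a, (cx, cy, cz) in enumerate(_CORNERS):
        g[:, a, 0] = cx * (1 + cy * xi[:, 1]) * (1 + cz * xi[:, 2]) / 8.0
        g[:, a, 1] = cy * (1 + cx * xi[:, 0]) * (1 + cz * xi[:, 2]) / 8.0
        g[:, a, 2] = cz * (1 + cx * xi[:, 0]) * (1 + cy * xi[:, 1]) / 8.0
    return g


GAUSS_DSHAPE = shape_gradients(GAUSS_PTS)      # (8, 8, 3)
CENTROID_DSHAPE = shape_gradients(CENTROID_PT)  # (1, 8, 3)


@dataclass(frozen=True)
class MeshSpec:
    """Mesh resolution: ``n_layers`` through-thickness layers (default 4),
    ``a`` angular divisions per 45-deg octant (core size ns = 2a),
    ``nt`` transition-band divisions and per-ring radial divisions."""

    n_layers: int = 4
    a: int = 2
    nt: int = 1
    ring_divisions: Optional[tuple] = None  # len == number of ring bands
    radial_factor: int = 1  # uniform multiplier on the radial divisions
    core_fraction: float = 0.5  # core half-width as a fraction of the first ring radius
    columns: str = "normal"  # through-thickness direction: "normal" | "vertical"

    def __post_init__(self):
        if self.n_layers < 1 or self.a < 1 or self.nt < 1 or self.radial_factor < 1:
            raise ValueError("n_layers, a, nt and radial_factor must be >= 1")

    @property
    def ns(self) -> int:
        return 2 * self.a

    def divisions(self, n_bands: int) -> np.ndarray:
        if self.ring_divisions is None:
            rd = np.ones(n_bands, dtype=int)
        else:
            rd = np.asarray(self.ring_divisions, dtype=int)
            if rd.size != n_bands or np.any(rd < 1):
                raise ValueError(f"ring_divisions must have {n_bands} entries >= 1")
        return rd * self.radial_factor

    def element_count(self, n_bands: int) -> int:
        rd = self.divisions(n_bands)
        return self.n_layers * (self.ns**2 + 4 * self.ns * self.nt + 8 * self.a * int(rd.sum()))

    def with_layers(self, n_layers: int) -> "MeshSpec":
        return MeshSpec(n_layers=n_layers, a=self.a, nt=self.nt,
                        ring_divisions=self.ring_divisions,
                        radial_factor=self.radial_factor,
                        core_fraction=self.core_fraction, columns=self.columns)

    def refined(self, factor: int = 2) -> "MeshSpec":
        """Uniform in-plane and through-thickness refinement."""
        rd = None if self.ring_divisions is None else tuple(
            int(r) * factor for r in self.ring_divisions)
        return MeshSpec(n_layers=self.n_layers * factor, a=self.a * factor,
                        nt=self.nt * factor, ring_divisions=rd,
                        radial_factor=self.radial_factor
                        if rd is not None else self.radial_factor * factor,
                        core_fraction=self.core_fraction)


@dataclass
class HexMesh:
    """Hexahedral corneal mesh with zone tags and boundary metadata."""

    nodes: np.ndarray            # (N, 3) coordinates (m)
    hexes: np.ndarray            # (E, 8) connectivity, VTK ordering
    zone: np.ndarray             # (E,) ZoneLabel ints
    octant: np.ndarray           # (E,)
    ring: np.ndarray             # (E,)
    fibers: FiberFrame           # per-element reference fiber frame
    facets: np.ndarray           # (F, 4) posterior pressure facets (outward CCW)
    rim: list                    # rim cross-section node-id arrays, one per station
    n_layers: int
    np2d: int                    # planform node count (nodes per layer)
    r_outer: float
    apex_anterior: int
    apex_posterior: int
    seg: SegmentationSpec = field(default_factory=SegmentationSpec)
    material_overrides: Optional[dict] = None  # {zone label int: MaterialParams}
    planform_r: Optional[np.ndarray] = None      # (np2d,) column anchor radius
    planform_theta: Optional[np.ndarray] = None  # (np2d,) column anchor angle

    def params_for(self, label):
        """Zone material constants, honoring per-mesh overrides."""
        from .zones import assign_parameters
        if self.material_overrides and int(label) in self.material_overrides:
            return self.material_overrides[int(label)]
        return assign_parameters(label)

    @property
    def n_nodes(self):
        return self.nodes.shape[0]

    @property
    def n_elements(self):
        return self.hexes.shape[0]

    def surface_nodes(self, surface: str) -> np.ndarray:
        """Node ids of one full surface layer (anterior = layer 0)."""
        if surface == "anterior":
            return np.arange(self.np2d)
        if surface == "posterior":
            return np.arange(self.np2d) + self.n_layers * self.np2d
        raise ValueError("surface must be 'anterior' or 'posterior'")

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.hexes].mean(axis=1)

    def with_coords(self, nodes: np.ndarray) -> "HexMesh":
        """Same topology, zone tags and fibers on updated coordinates."""
        return HexMesh(nodes=np.array(nodes, dtype=float), hexes=self.hexes,
                       zone=self.zone, octant=self.octant, ring=self.ring,
                       fibers=self.fibers, facets=self.facets, rim=self.rim,
                       n_layers=self.n_layers, np2d=self.np2d,
                       r_outer=self.r_outer, apex_anterior=self.apex_anterior,
                       apex_posterior=self.apex_posterior, seg=self.seg,
                       material_overrides=self.material_overrides,
                       planform_r=self.planform_r,
                       planform_theta=self.planform_theta)


def _planform(seg: SegmentationSpec, spec: MeshSpec):
    """2D butterfly mesh of the disc: nodes (m) and CCW quads."""
    a, ns, nt = spec.a, spec.ns, spec.nt
    n_ang = 8 * a
    phi0 = np.deg2rad(22.5)
    theta = phi0 + np.arange(n_ang) * (2 * np.pi / n_ang)

    circles = np.append(seg.ring_radii, seg.r_limbus_outer)  # r1..r_outer
    r1 = circles[0]
    s = spec.core_fraction * r1

    # square-core boundary: Chebyshev projection in the frame rotated by 22.5 deg
    rot = np.deg2rad(22.5)
    c, sn = np.cos(rot), np.sin(rot)
    ang = theta - rot
    d = np.column_stack([np.cos(ang), np.sin(ang)])
    scale = s / np.max(np.abs(d), axis=1)
    p_rot = d * scale[:, None]
    b = p_rot @ np.array([[c, sn], [-sn, c]])  # rotate back: p = R(rot) p_rot

    nodes = []
    # --- core grid via transfinite interpolation -------------------------
    G = np.full((ns + 1, ns + 1), -1, dtype=int)
    corner_j = a  # boundary index of the rotated-frame (s, s) corner
    coords = {}

    def bput(i, k, j):
        coords[(i, k)] = b[j % n_ang]

    for t in range(ns + 1):
        bput(ns - t, ns, corner_j + t)          # top edge
        bput(0, ns - t, corner_j + 2 * a + t)   # left edge
        bput(t, 0, corner_j + 4 * a + t)        # bottom edge
        bput(ns, t, corner_j + 6 * a + t)       # right edge
    for i in range(ns + 1):
        for k in range(ns + 1):
            if (i, k) in coords:
                continue
            xi, eta = i / ns, k / ns
            B, T = coords[(i, 0)], coords[(i, ns)]
            Lh, R = coords[(0, k)], coords[(ns, k)]
            P00, P10 = coords[(0, 0)], coords[(ns, 0)]
            P01, P11 = coords[(0, ns)], coords[(ns, ns)]
            coords[(i, k)] = ((1 - eta) * B + eta * T + (1 - xi) * Lh + xi * R
                              - ((1 - xi) * (1 - eta) * P00 + xi * (1 - eta) * P10
                                 + (1 - xi) * eta * P01 + xi * eta * P11))
    for i in range(ns + 1):
        for k in range(ns + 1):
            G[i, k] = len(nodes)
            nodes.append(coords[(i, k)])

    # boundary ring node ids of the core, ordered by boundary index j
    ring0 = np.empty(n_ang, dtype=int)
    for t in range(ns):
        ring0[(corner_j + t) % n_ang] = G[ns - t, ns]
        ring0[(corner_j + 2 * a + t) % n_ang] = G[0, ns - t]
        ring0[(corner_j + 4 * a + t) % n_ang] = G[t, 0]
        ring0[(corner_j + 6 * a + t) % n_ang] = G[ns, t]

    quads = []
    for i in range(ns):
        for k in range(ns):
            quads.append([G[i, k], G[i + 1, k], G[i + 1, k + 1], G[i, k + 1]])

    def add_ring(pts):
        ids = np.arange(len(nodes), len(nodes) + n_ang)
        nodes.extend(pts)
        return ids

    def band(inner_ids, ndiv, r_to):
        """Quads between an inner ring and ndiv new rings ending on r_to."""
        prev = inner_ids
        inner_pts = np.array([nodes[i] for i in inner_ids])
        target = np.column_stack([r_to * np.cos(theta), r_to * np.sin(theta)])
        for t in range(1, ndiv + 1):
            f = t / ndiv
            pts = (1 - f) * inner_pts + f * target
            cur = add_ring(pts)
            for j in range(n_ang):
                jp = (j + 1) % n_ang
                quads.append([prev[j], cur[j], cur[jp], prev[jp]])
            prev = cur
        return prev

    # transition band: square boundary -> first circle, then annular bands
    prev = band(ring0, nt, r1)
    n_bands = circles.size - 1
    rdiv = spec.divisions(n_bands)
    for bi in range(n_bands):
        prev = band(prev, int(rdiv[bi]), circles[bi + 1])

    nodes = np.asarray(nodes, dtype=float)
    quads = np.asarray(quads, dtype=int)
    # quad orientation check: CCW (positive area)
    v1 = nodes[quads[:, 1]] - nodes[quads[:, 0]]
    v2 = nodes[quads[:, 3]] - nodes[quads[:, 0]]
    if np.any(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0] <= 0):
        raise MeshingError("planform mesh contains a non-CCW quad")
    return nodes, quads, prev  # prev = outermost ring ids


def _surface_intersection(zfun, anchor, d, t0, n_iter=60):
    """Parameter t with anchor + t d on the graph z = zfun(r, theta).

    Fixed-point iteration t <- (z(r(t)) - z_anchor)/d_z; contracts whenever
    the column is steeper than the surface (guaranteed by the limbus-angle
    flattening of the fixtures).
    """
    t = t0.copy()
    for _ in range(n_iter):
        xy = anchor[:, :2] + t[:, None] * d[:, :2]
        r = np.hypot(xy[:, 0], xy[:, 1])
        th = np.arctan2(xy[:, 1], xy[:, 0])
        t_new = (zfun(r, th) - anchor[:, 2]) / d[:, 2]
        if np.max(np.abs(t_new - t)) < 1e-15:
            t = t_new
            break
        t = t_new
    return t


def generate_mesh(geometry: CornealGeometry,
                  seg: SegmentationSpec = SegmentationSpec(),
                  spec: MeshSpec = MeshSpec()) -> HexMesh:
    """Mesh the corneal solid; every element is zone-tagged at its centroid.

    Node columns are anchored at the mid-surface over the planform circles
    (so ring/sector boundaries are mesh faces) and run along the local
    mid-surface normal (``spec.columns == "normal"``; the rim columns thereby
    form the corneo-scleral cut cone normal to the limbus-angle interface) or
    vertically (``"vertical"``, for analytic benchmark solids).  Column ends
    lie exactly on the anterior/posterior surfaces; layers are equally
    spaced along each column.
    """
    p2d, quads, outer_ids = _planform(seg, spec)
    np2d = p2d.shape[0]
    L = spec.n_layers

    r2d = np.hypot(p2d[:, 0], p2d[:, 1])
    th2d = np.arctan2(p2d[:, 1], p2d[:, 0])
    za = geometry.z_ant(r2d, th2d)
    zp = geometry.z_post(r2d, th2d)
    zmid = 0.5 * (za + zp)
    anchor = np.column_stack([p2d[:, 0], p2d[:, 1], zmid])

    if spec.columns == "vertical":
        d = np.tile([0.0, 0.0, 1.0], (np2d, 1))
    elif spec.columns == "normal":
        h = 1e-6

        def zmid_xy(x, y):
            r = np.hypot(x, y)
            th = np.arctan2(y, x)
            return 0.5 * (geometry.z_ant(r, th) + geometry.z_post(r, th))

        zx = (zmid_xy(p2d[:, 0] + h, p2d[:, 1])
              - zmid_xy(p2d[:, 0] - h, p2d[:, 1])) / (2 * h)
        zy = (zmid_xy(p2d[:, 0], p2d[:, 1] + h)
              - zmid_xy(p2d[:, 0], p2d[:, 1] - h)) / (2 * h)
        d = np.column_stack([-zx, -zy, np.ones(np2d)])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
    else:
        raise ValueError("columns must be 'normal' or 'vertical'")

    t_vert = zp - za
    t_a = _surface_intersection(geometry.z_ant, anchor, d, -0.5 * t_vert * d[:, 2])
    t_p = _surface_intersection(geometry.z_post, anchor, d, 0.5 * t_vert * d[:, 2])
    if np.any(t_p <= t_a):
        raise MeshingError("degenerate through-thickness column")

    nodes = np.empty(((L + 1) * np2d, 3))
    for layer in range(L + 1):
        f = layer / L
        t = t_a + f * (t_p - t_a)
        nodes[layer * np2d:(layer + 1) * np2d] = anchor + t[:, None] * d

    hexes = np.empty((L * quads.shape[0], 8), dtype=int)
    e = 0
    for layer in range(L):
        lo, hi = layer * np2d, (layer + 1) * np2d
        for q in quads:
            hexes[e, :4] = q + lo
            hexes[e, 4:] = q + hi
            e += 1

    # posterior pressure facets (outward normals toward the anterior chamber)
    facets = quads + L * np2d

    # rim cross-sections: one node column through the thickness per station
    rim = [np.array([layer * np2d + j for layer in range(L + 1)])
           for j in outer_ids]

    # zone classification at element centroids (mid-thickness planform radius)
    cent = nodes[hexes].mean(axis=1)
    cent_cl = cent.copy()
    rc = np.hypot(cent_cl[:, 0], cent_cl[:, 1])
    over = rc > seg.r_limbus_outer
    if over.any():  # rim tilt can push outer centroids slightly past the extent
        shrink = seg.r_limbus_outer / rc[over]
        cent_cl[over, 0] *= shrink
        cent_cl[over, 1] *= shrink
    octant, ring, zone = classify_point(cent_cl, seg)
    fibers = fiber_frame(cent, zone)

    apex2d = int(np.argmin(r2d))
    mesh = HexMesh(nodes=nodes, hexes=hexes, zone=zone, octant=octant,
                   ring=ring, fibers=fibers, facets=facets, rim=rim,
                   n_layers=L, np2d=np2d, r_outer=seg.r_limbus_outer,
                   apex_anterior=apex2d, apex_posterior=L * np2d + apex2d,
                   seg=seg, planform_r=r2d, planform_theta=th2d)

    detJ = hex_jacobians(mesh)
    if np.any(detJ <= 0):
        bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
        raise MeshingError(f"inverted element {bad} (non-positive Jacobian)", element=bad)
    return mesh


def hex_jacobians(mesh: HexMesh) -> np.ndarray:
    """det of the isoparametric Jacobian at the 8 Gauss points, (E, 8)."""
    Xe = mesh.nodes[mesh.hexes]                      # (E, 8, 3)
    J = np.einsum("gai,eaj->egij", GAUSS_DSHAPE, Xe)  # (E, 8, 3, 3) dX/dxi^T
    return np.linalg.det(J)


def hex_volumes(mesh: HexMesh) -> np.ndarray:
    return hex_jacobians(mesh).sum(axis=1)  # unit Gauss weights


def posterior_facets(mesh: HexMesh) -> np.ndarray:
    return mesh.facets


def rim_sections(mesh: HexMesh) -> list:
    return mesh.rim


def facet_vector_areas(nodes: np.ndarray, facets: np.ndarray) -> np.ndarray:
    """Exact vector area 0.5 (d1 x d2) of each bilinear quad facet."""
    x = nodes[facets]
    d1 = x[:, 2] - x[:, 0]
    d2 = x[:, 3] - x[:, 1]
    return 0.5 * np.cross(d1, d2)
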