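"""Multizone corneal segmentation, zone material parameters and fiber frames.

The corneal planform is split into 8 azimuthal sectors of 45 deg (half-width
22.5 deg) centred on the nasal-temporal (x) and superior-inferior (y)
meridians, and into circumferential rings bounded by cones of diameter
2, 4, 6, 8, 10 and 11 mm measured at mid-thickness; the limbus band runs
from the 11 mm diameter to the outer boundary.  Each cell carries one of
four material rows:

    CENTRAL_NT_SI_STRONG  k1 = 50 kPa   central disc (<= 4 mm diameter),
                                        N-T and S-I sectors out to the limbus
    CENTRAL_OBLIQUE       k1 = 25 kPa   oblique sectors, 4-8 mm diameter
    TRANSITION            k1 = 37.5 kPa oblique sectors, 8-11 mm diameter
    LIMBUS                k1 = 50 kPa   beyond 11 mm, single circumferential
                                        fiber family

a1 = 40 kPa and a2 = -10 kPa (matrix) and k2 = 200 are shared by all zones;
the bulk factor k0 = 5.5 MPa is global.  Fiber frames are nasal-temporal /
superior-inferior unit vectors in the corneal zones and the circumferential
tangent in the limbus.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .material import MaterialParams

__all__ = [
    "ZoneLabel",
    "SegmentationSpec",
    "FiberFrame",
    "classify_point",
    "assign_parameters",
    "fiber_frame",
    "control_points",
    "control_point_ids",
]


class ZoneLabel(enum.IntEnum):
    CENTRAL_NT_SI_STRONG = 0
    TRANSITION = 1
    CENTRAL_OBLIQUE = 2
    LIMBUS = 3


# Table of zone constants; a1/a2/k2/k0 shared, k1 varies with fiber density.
_ZONE_PARAMS = {
    ZoneLabel.CENTRAL_NT_SI_STRONG: MaterialParams(k1=50_000.0),
    ZoneLabel.TRANSITION: MaterialParams(k1=37_500.0),
    ZoneLabel.CENTRAL_OBLIQUE: MaterialParams(k1=25_000.0),
    ZoneLabel.LIMBUS: MaterialParams(k1=50_000.0).single_family(),
}


@dataclass(frozen=True)
class SegmentationSpec:
    """Ring/sector layout of the multizone model.

    ``ring_diameters_mm`` are the cone diameters bounding the circumferential
    zones; the last one (11 mm) starts the limbus.  ``sector_half_width_deg``
    is the half-width of the sectors around the principal meridians.
    ``r_limbus_outer`` is the outer extent of the meshed solid (m).
    ``strong_oblique_max_diameter_mm`` controls how far out the central
    strong label extends in the oblique sectors (the 2-4 mm oblique cells
    default to the strong row); ``transition_min_diameter_mm`` is where the
    oblique sectors switch from the weak oblique row to the transition row.
    """

    ring_diameters_mm: tuple = (2.0, 4.0, 6.0, 8.0, 10.0, 11.0)
    sector_half_width_deg: float = 22.5
    r_limbus_outer: float = 6.25e-3
    strong_oblique_max_diameter_mm: float = 4.0
    transition_min_diameter_mm: float = 8.0

    def __post_init__(self):
        d = np.asarray(self.ring_diameters_mm, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("ring diameters must be strictly increasing")
        if self.r_limbus_outer <= d[-1] * 1e-3 / 2:
            raise ValueError("limbus outer extent must lie beyond the last ring diameter")

    @property
    def ring_radii(self) -> np.ndarray:
        """Ring boundary radii in meters (m), excluding the outer extent."""
        return np.asarray(self.ring_diameters_mm, dtype=float) * 1e-3 / 2.0

    @property
    def r_limbus(self) -> float:
        """Radius where the limbus band starts (m)."""
        return float(self.ring_radii[-1])


@dataclass
class FiberFrame:
    """Unit reference fiber directions per element (or per point)."""

    m0: np.ndarray
    n0: np.ndarray
    active: np.ndarray  # (..., 2) bool: family activity flags


def classify_point(x, spec: SegmentationSpec = SegmentationSpec()):
    """Classify positions into (octant id, ring id, ZoneLabel) — vectorized.

    Octants are indexed 0..7 counterclockwise starting from the sector
    centred on +x (nasal-temporal); even octants straddle the principal
    meridians, odd octants are oblique.  Ring membership uses the in-plane
    (mid-thickness) radius with half-open intervals [d_i, d_{i+1}); boundary
    points fall in the outer ring.
    """
    x = np.asarray(x, dtype=float)
    r = np.hypot(x[..., 0], x[..., 1])
    theta = np.arctan2(x[..., 1], x[..., 0])
    half = np.deg2rad(spec.sector_half_width_deg)
    octant = np.floor_divide(np.mod(theta + half, 2 * np.pi), 2 * half).astype(int) % 8

    radii = spec.ring_radii
    if np.any(r > spec.r_limbus_outer * (1 + 1e-9)):
        raise ValueError("point outside the limbus outer extent")
    ring = np.searchsorted(radii, r, side="right")  # 0..len(radii)

    oblique = octant % 2 == 1
    r_strong = spec.strong_oblique_max_diameter_mm * 1e-3 / 2.0
    r_trans = spec.transition_min_diameter_mm * 1e-3 / 2.0

    label = np.full(r.shape, int(ZoneLabel.CENTRAL_NT_SI_STRONG))
    label[(oblique) & (r > r_strong) & (r < r_trans)] = int(ZoneLabel.CENTRAL_OBLIQUE)
    label[(oblique) & (r >= r_trans) & (r < spec.r_limbus)] = int(ZoneLabel.TRANSITION)
    label[r >= spec.r_limbus] = int(ZoneLabel.LIMBUS)
    if label.ndim == 0:
        return int(octant), int(ring), ZoneLabel(int(label))
    return octant, ring, label


def assign_parameters(label: ZoneLabel) -> MaterialParams:
    """Material constants of a zone row."""
    try:
        return _ZONE_PARAMS[ZoneLabel(label)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown zone label {label!r}") from None


def fiber_frame(centroids: np.ndarray, labels: np.ndarray) -> FiberFrame:
    """Reference fiber directions at element centroids (vectorized).

    Corneal zones: m0 = +x (nasal-temporal), n0 = +y (superior-inferior).
    Limbus: m0 = circumferential tangent (-sin t, cos t, 0), second family
    inactive.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    n = centroids.shape[0]
    m0 = np.tile([1.0, 0.0, 0.0], (n, 1))
    n0 = np.tile([0.0, 1.0, 0.0], (n, 1))
    active = np.ones((n, 2), dtype=bool)
    limb = labels == int(ZoneLabel.LIMBUS)
    if limb.any():
        th = np.arctan2(centroids[limb, 1], centroids[limb, 0])
        m0[limb] = np.column_stack([-np.sin(th), np.cos(th), np.zeros(th.size)])
        active[limb, 1] = False
    return FiberFrame(m0=m0, n0=n0, active=active)


def control_point_ids(mesh, spec: SegmentationSpec = SegmentationSpec(),
                      surface: str = "anterior",
                      n_meridians: int = 8,
                      circles: Optional[np.ndarray] = None) -> np.ndarray:
    """Node ids of the control set on one surface.

    The control set is the apex node plus every node whose through-thickness
    column is anchored where a sector-boundary meridian crosses a
    ring-boundary circle (the six ring diameters plus the limbus outer
    boundary): 8 x 7 + 1 = 57 nodes with the default layout.  Matching uses
    the planform column parameters (mid-thickness anchors), which the mesher
    places on the boundary circles exactly.
    """
    if surface not in ("anterior", "posterior"):
        raise ValueError("surface must be 'anterior' or 'posterior'")
    if mesh.planform_r is None:
        raise ValueError("mesh is not zone-conforming: no planform parameters")
    ids = mesh.surface_nodes(surface)
    r = mesh.planform_r
    theta = np.mod(mesh.planform_theta, 2 * np.pi)

    if circles is None:
        circles = np.append(spec.ring_radii, mesh.r_outer)
    half = np.deg2rad(spec.sector_half_width_deg)
    meridians = np.mod(half + np.arange(n_meridians) * 2 * np.pi / n_meridians,
                       2 * np.pi)

    picked = [ids[np.argmin(r)]]  # apex node
    for rc in circles:
        on_circle = np.abs(r - rc) < max(1e-9, 1e-9 * rc)
        if not on_circle.any():
            raise ValueError(
                f"mesh is not zone-conforming: no node columns on circle r={rc:.4g} m")
        for tm in meridians:
            dt = np.abs(np.mod(theta - tm + np.pi, 2 * np.pi) - np.pi)
            sel = on_circle & (dt < 1e-9)
            if not sel.any():
                raise ValueError(
                    f"mesh is not zone-conforming: no node column at meridian "
                    f"{np.rad2deg(tm):.1f} deg on circle r={rc:.4g} m")
            picked.append(ids[np.argmax(sel)])
    return np.unique(np.asarray(picked))


def control_points(mesh, spec: SegmentationSpec = SegmentationSpec(),
                   surface: str = "anterior", **kwargs) -> np.ndarray:
    """Coordinates of the control nodes (ordered by node id)."""
    return mesh.nodes[control_point_ids(mesh, spec, surface, **kwargs)]
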