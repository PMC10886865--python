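"""Synthetic corneal geometries and topographer-style polar elevation grids.

The cornea is modelled as the solid between two smooth elevation surfaces
``z = z_ant(r, theta)`` (anterior) and ``z = z_post(r, theta)`` (posterior),
expressed in a Cartesian frame with the apex at the origin, the optical axis
along +z pointing toward the interior of the eye (posterior side), x along
the nasal-temporal direction and y along the superior-inferior direction.
All lengths are SI meters.

Healthy corneas are biconic caps; keratoconus is emulated by a decentred
Gaussian protrusion of both surfaces combined with local stromal thinning.
A polar (meridian x radius) elevation grid mimicking a Sirius-type
topographer export can be sampled from any geometry, serialized as CSV, and
refitted into a smooth surface pair by periodic polar spline interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "BiconicParams",
    "ConePerturbation",
    "TopographyGrid",
    "CornealGeometry",
    "GeometryInfeasibleError",
    "make_cornea",
    "to_topography",
    "from_topography",
    "keratoconus_grade",
    "default_anterior",
    "default_posterior",
    "DEFAULT_CENTRAL_THICKNESS",
    "DEFAULT_LIMBUS_ANGLE",
]

#: Central corneal thickness of the default healthy fixture (m).
DEFAULT_CENTRAL_THICKNESS = 5.5e-4
#: Corneo-scleral interface angle (rad); an average of 40 degrees.
DEFAULT_LIMBUS_ANGLE = np.deg2rad(40.0)


class GeometryInfeasibleError(ValueError):
    """Raised when a requested geometry is not a valid solid (e.g. the
    posterior surface crosses the anterior one after cone thinning)."""


@dataclass(frozen=True)
class BiconicParams:
    """Biconic surface parameters.

    The sag of a biconic surface is

        z(x, y) = (x^2/Rx + y^2/Ry) /
                  (1 + sqrt(1 - (1+Qx) x^2/Rx^2 - (1+Qy) y^2/Ry^2))

    with apical radii ``Rx, Ry`` (m) and asphericities ``Qx, Qy``.
    ``offset`` shifts the apex along the optical axis: 0 for the anterior
    surface, the central corneal thickness for the posterior one.
    """

    Rx: float
    Ry: float
    Qx: float = 0.0
    Qy: float = 0.0
    role: str = "anterior"  # anterior | posterior
    offset: float = 0.0

    def __post_init__(self):
        if self.Rx <= 0 or self.Ry <= 0:
            raise ValueError("apical radii must be positive")
        if self.role not in ("anterior", "posterior"):
            raise ValueError(f"unknown surface role {self.role!r}")

    def sag(self, x, y):
        """Vectorized sag (without the axial offset)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        num = x**2 / self.Rx + y**2 / self.Ry
        arg = 1.0 - (1.0 + self.Qx) * x**2 / self.Rx**2 - (1.0 + self.Qy) * y**2 / self.Ry**2
        if np.any(arg <= 0.0):
            raise GeometryInfeasibleError("biconic surface evaluated beyond its valid aperture")
        return num / (1.0 + np.sqrt(arg))


@dataclass(frozen=True)
class ConePerturbation:
    """Decentred keratoconus-like protrusion with stromal thinning.

    ``amplitude`` (m) is the outward elevation of the anterior surface at the
    cone centre, located at polar position ``(r0, theta0)`` with Gaussian
    width ``sigma`` (m).  ``thinning`` in [0, 1) removes that fraction of the
    local thickness at the cone centre (posterior surface bulging forward
    more than the anterior one).
    """

    amplitude: float
    r0: float = 1.5e-3
    theta0: float = 0.0
    sigma: float = 1.5e-3
    thinning: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("cone amplitude must be >= 0")
        if self.sigma <= 0:
            raise ValueError("cone width must be > 0")
        if not (0.0 <= self.thinning < 1.0):
            raise ValueError("thinning fraction must lie in [0, 1)")

    def gaussian(self, r, theta):
        """Gaussian bump weight at polar coordinates (vectorized)."""
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        d2 = r**2 + self.r0**2 - 2.0 * r * self.r0 * np.cos(theta - self.theta0)
        return np.exp(-d2 / (2.0 * self.sigma**2))


@dataclass
class CornealGeometry:
    """Evaluable corneal solid: two single-valued elevation surfaces.

    ``z_ant`` and ``z_post`` take polar coordinates ``(r, theta)`` (vectorized)
    and return elevations in meters; ``thickness(r, theta) = z_post - z_ant``.
    """

    z_ant: Callable[[np.ndarray, np.ndarray], np.ndarray]
    z_post: Callable[[np.ndarray, np.ndarray], np.ndarray]
    r_max: float
    central_thickness: float
    limbus_angle: float = DEFAULT_LIMBUS_ANGLE
    meta: dict = field(default_factory=dict)

    def thickness(self, r, theta):
        return self.z_post(r, theta) - self.z_ant(r, theta)

    def min_thickness(self, n_r: int = 120, n_theta: int = 180) -> float:
        r = np.linspace(0.0, self.r_max, n_r)
        th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
        R, T = np.meshgrid(r, th, indexing="ij")
        return float(np.min(self.thickness(R, T)))


def default_anterior(R: float = 7.8e-3, Q: float = 0.0) -> BiconicParams:
    """Standard-literature healthy anterior surface (fixture, not a claim)."""
    return BiconicParams(Rx=R, Ry=R, Qx=Q, Qy=Q, role="anterior", offset=0.0)


def default_posterior(R: float = 6.5e-3, Q: float = 0.0,
                      cct: float = DEFAULT_CENTRAL_THICKNESS) -> BiconicParams:
    return BiconicParams(Rx=R, Ry=R, Qx=Q, Qy=Q, role="posterior", offset=cct)


def make_cornea(
    biconic_ant: BiconicParams,
    biconic_post: BiconicParams,
    cone: Optional[ConePerturbation] = None,
    limbus_angle: float = DEFAULT_LIMBUS_ANGLE,
    r_max: float = 6.25e-3,
    min_thickness: float = 5.0e-5,
    max_thickness: float = 9.0e-4,
    peripheral_flatten_r: Optional[float] = 4.5e-3,
) -> CornealGeometry:
    """Build a corneal solid from two biconics and an optional cone.

    The anterior protrudes outward (toward -z) by ``A*G`` and the posterior by
    ``A*G + tf*cct*G`` so that the local thickness at the cone centre is
    ``cct*(1 - tf)`` plus the biconic sag correction.

    Two peripheral corrections make the solid shell-like out to the limbus,
    as real corneas are and as pure biconics extended to an 11+ mm aperture
    are not:

    * beyond ``peripheral_flatten_r`` the surfaces blend smoothly (C1) into
      a cone whose inclination at ``r_max`` equals ``limbus_angle`` — the
      corneo-scleral interface inclination, 40 degrees on average.  Pass
      ``None`` to keep the raw biconics (analytic benchmark geometries).
    * the thickness (the posterior biconic steepens far faster than the
      anterior one) saturates smoothly at ``max_thickness``, leaving the
      central region untouched.
    """
    cct = biconic_post.offset - biconic_ant.offset
    if cct <= 0:
        raise GeometryInfeasibleError("central corneal thickness must be positive")
    if max_thickness <= cct:
        raise GeometryInfeasibleError("max_thickness must exceed the central thickness")

    def _flatten(z_raw, r, theta, sag_fn):
        """C1 blend of a raw sag surface into the limbus-angle cone."""
        if peripheral_flatten_r is None:
            return z_raw
        r_f = peripheral_flatten_r
        s = np.clip((r - r_f) / (r_max - r_f), 0.0, 1.0)
        phi = s * s * (3.0 - 2.0 * s)  # smoothstep: C1 at both ends
        h = 1e-7
        z_f = sag_fn(r_f, theta)
        slope_f = (sag_fn(r_f + h, theta) - sag_fn(r_f - h, theta)) / (2 * h)
        # tangent continuation steered to the interface inclination at r_max
        t_lim = np.tan(limbus_angle)
        z_cone = z_f + slope_f * (r - r_f) + 0.5 * (t_lim - slope_f) * \
            (r - r_f) ** 2 / (r_max - r_f)
        return np.where(r <= r_f, z_raw, (1 - phi) * z_raw + phi * z_cone)

    def _ant_sag(r, theta):
        x, y = r * np.cos(theta), r * np.sin(theta)
        return biconic_ant.offset + biconic_ant.sag(x, y)

    def _ant_base(r, theta):
        return _flatten(_ant_sag(r, theta), r, theta, _ant_sag)

    def _thickness_uncapped(r, theta):
        x, y = r * np.cos(theta), r * np.sin(theta)
        # posterior biconic evaluated safely: beyond its aperture the raw
        # thickness is far above the cap anyway, so a large sentinel is fine
        arg = (1.0 - (1.0 + biconic_post.Qx) * x**2 / biconic_post.Rx**2
               - (1.0 + biconic_post.Qy) * y**2 / biconic_post.Ry**2)
        safe = arg > 0.05
        num = x**2 / biconic_post.Rx + y**2 / biconic_post.Ry
        sag_post = np.where(
            safe, num / (1.0 + np.sqrt(np.where(safe, arg, 1.0))), 0.0)
        t = (biconic_post.offset + sag_post
             - biconic_ant.offset - biconic_ant.sag(x, y))
        return np.where(safe, t, 10.0 * max_thickness)

    def _cap(t):
        # smooth saturation: identity near zero, -> max_thickness at infinity
        x = t / max_thickness
        return max_thickness * x / (1.0 + x**6) ** (1.0 / 6.0)

    def z_ant(r, theta):
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        z = _ant_base(r, theta)
        if cone is not None and cone.amplitude > 0:
            z = z - cone.amplitude * cone.gaussian(r, theta)
        return z

    def z_post(r, theta):
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        z = _ant_base(r, theta) + _cap(_thickness_uncapped(r, theta))
        if cone is not None:
            g = cone.gaussian(r, theta)
            z = z - (cone.amplitude + cone.thinning * cct) * g
        return z

    geom = CornealGeometry(
        z_ant=z_ant, z_post=z_post, r_max=r_max, central_thickness=cct,
        limbus_angle=limbus_angle,
        meta={"anterior": biconic_ant, "posterior": biconic_post, "cone": cone},
    )
    tmin = geom.min_thickness()
    if tmin <= 0:
        raise GeometryInfeasibleError(
            f"cone thinning makes the posterior surface cross the anterior one "
            f"(min thickness {tmin:.3e} m)")
    if tmin < min_thickness:
        raise GeometryInfeasibleError(
            f"minimum thickness {tmin:.3e} m below configured floor {min_thickness:.3e} m")
    return geom


# Keratoconus grade emulation: (amplitude m, thinning fraction) increasing
# monotonically with Amsler-Krumeich grade.  A fixture convention only.
_GRADE_MAP = {
    "G1": (2.0e-5, 0.10),
    "G2": (4.0e-5, 0.15),
    "G3": (7.0e-5, 0.22),
    "G4": (1.1e-4, 0.30),
}


def keratoconus_grade(grade: str, r0: float = 1.5e-3,
                      theta0: float = np.deg2rad(-60.0),
                      sigma: float = 1.5e-3) -> CornealGeometry:
    """Synthetic keratoconic cornea emulating grade G1..G4 severity.

    The cone sits infero-temporally by default, the usual clinical location.
    """
    try:
        amp, tf = _GRADE_MAP[grade.upper()]
    except KeyError:
        raise ValueError(f"unknown keratoconus grade {grade!r}; expected G1..G4") from None
    cone = ConePerturbation(amplitude=amp, r0=r0, theta0=theta0, sigma=sigma, thinning=tf)
    return make_cornea(default_anterior(), default_posterior(), cone=cone)


# ---------------------------------------------------------------------------
# Topography grids
# ---------------------------------------------------------------------------

@dataclass
class TopographyGrid:
    """Rectangular polar elevation grid (meridian x radius), Sirius-style.

    ``theta`` are uniform meridian angles (rad, length M, no wrap duplicate);
    ``r`` are radial samples (m, length N, ascending, starting at 0);
    ``z_ant``/``z_post`` have shape (M, N).  NaN marks missing samples.
    """

    theta: np.ndarray
    r: np.ndarray
    z_ant: np.ndarray
    z_post: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.z_ant = np.asarray(self.z_ant, dtype=float)
        self.z_post = np.asarray(self.z_post, dtype=float)
        M, N = self.theta.size, self.r.size
        if self.z_ant.shape != (M, N) or self.z_post.shape != (M, N):
            raise ValueError("non-rectangular topography grid")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("radial samples must be strictly increasing")

    def fill_missing(self) -> "TopographyGrid":
        """Fill NaN cells by periodic linear interpolation along meridians."""
        z_ant = _fill_periodic(self.z_ant)
        z_post = _fill_periodic(self.z_post)
        return TopographyGrid(self.theta, self.r, z_ant, z_post)

    # -- CSV serialization: header theta_rad,r_m,z_ant_m,z_post_m,
    #    row-major meridian-then-radius ordering ------------------------------
    def to_csv(self, path) -> None:
        M, N = self.theta.size, self.r.size
        T = np.repeat(self.theta, N)
        R = np.tile(self.r, M)
        data = np.column_stack([T, R, self.z_ant.ravel(), self.z_post.ravel()])
        np.savetxt(path, data, delimiter=",", comments="",
                   header="theta_rad,r_m,z_ant_m,z_post_m", fmt="%.17e")

    @classmethod
    def from_csv(cls, path) -> "TopographyGrid":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        theta = np.unique(data[:, 0])
        r = np.unique(data[:, 1])
        M, N = theta.size, r.size
        if data.shape[0] != M * N:
            raise ValueError("CSV does not contain a complete rectangular grid")
        order = np.lexsort((data[:, 1], data[:, 0]))
        data = data[order]
        return cls(theta, r, data[:, 2].reshape(M, N), data[:, 3].reshape(M, N))


def _fill_periodic(z: np.ndarray) -> np.ndarray:
    """Column-wise NaN fill by linear interpolation periodic in the meridian
    index; falls back to the radial column mean if a whole ring is missing."""
    z = z.copy()
    M = z.shape[0]
    for j in range(z.shape[1]):
        col = z[:, j]
        bad = np.isnan(col)
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"radial ring {j} has no valid samples to interpolate from")
        idx = np.arange(M)
        good = ~bad
        # periodic extension for wrap-around interpolation
        xg = np.concatenate([idx[good] - M, idx[good], idx[good] + M])
        yg = np.tile(col[good], 3)
        z[bad, j] = np.interp(idx[bad], xg, yg)
    return z


def to_topography(geometry: CornealGeometry, n_meridians: int = 24,
                  n_radial: int = 32) -> TopographyGrid:
    """Sample a geometry on a polar grid, as a topographer would report it."""
    if n_meridians < 8 or n_radial < 8:
        raise ValueError("at least 8 meridians and 8 radial samples are required")
    theta = np.linspace(0.0, 2 * np.pi, n_meridians, endpoint=False)
    r = np.linspace(0.0, geometry.r_max, n_radial)
    R, T = np.meshgrid(r, theta, indexing="xy")  # (M, N)
    return TopographyGrid(theta, r, geometry.z_ant(R, T), geometry.z_post(R, T))


class _PolarSplineSurface:
    """Smooth single-valued surface from a polar grid.

    Interpolation is a periodic cubic spline along each radial ring followed
    by a cubic spline in the radius; this reproduces the grid exactly at the
    knots and keeps the gradient continuous across the theta wrap.
    """

    def __init__(self, theta: np.ndarray, r: np.ndarray, z: np.ndarray):
        self.theta = theta
        self.r = r
        # periodic ring splines need the wrap sample appended
        th_ext = np.append(theta, theta[0] + 2 * np.pi)
        self._rings = [
            CubicSpline(th_ext, np.append(z[:, j], z[0, j]), bc_type="periodic")
            for j in range(r.size)
        ]

    def __call__(self, r, th):
        r = np.asarray(r, dtype=float)
        th = np.mod(np.asarray(th, dtype=float), 2 * np.pi)
        shape = np.broadcast(r, th).shape
        rq = np.broadcast_to(r, shape).ravel()
        tq = np.broadcast_to(th, shape).ravel()
        # ring values at each query angle: (n_rings, n_query)
        vals = np.vstack([s(tq) for s in self._rings])
        out = np.empty(rq.size)
        # group queries by identical angle is uncommon; spline per query in r.
        # Vectorize by interpolating all queries against the shared radial knots
        # using local cubic (Catmull-Rom-like) via CubicSpline on the column.
        # Columns differ per query, so evaluate with a single pass of
        # polynomial interpolation: build one spline per query (cheap, small N).
        for k in range(rq.size):
            out[k] = CubicSpline(self.r, vals[:, k])(rq[k])
        return out.reshape(shape)


def from_topography(grid: TopographyGrid) -> CornealGeometry:
    """Refit a topography grid into a smooth corneal solid.

    Missing (NaN) samples are filled by interpolation first.  The returned
    surfaces interpolate the grid exactly at the knots.
    """
    if np.isnan(grid.z_ant).any() or np.isnan(grid.z_post).any():
        grid = grid.fill_missing()
    # enforce a single apex elevation shared by all meridians at r=0
    z_ant = grid.z_ant.copy()
    z_post = grid.z_post.copy()
    if grid.r[0] == 0.0:
        z_ant[:, 0] = z_ant[:, 0].mean()
        z_post[:, 0] = z_post[:, 0].mean()
    ant = _PolarSplineSurface(grid.theta, grid.r, z_ant)
    post = _PolarSplineSurface(grid.theta, grid.r, z_post)
    cct = float(post(0.0, 0.0) - ant(0.0, 0.0))
    return CornealGeometry(
        z_ant=ant, z_post=post, r_max=float(grid.r[-1]), central_thickness=cct,
        meta={"source": "topography"},
    )
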