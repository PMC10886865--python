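"""Synthetic corneal geometries and topography grids."""
import numpy as np
import pytest

import keratofem.geometry as gg
from keratofem.geometry import (BiconicParams, ConePerturbation,
                                GeometryInfeasibleError, TopographyGrid,
                                from_topography, keratoconus_grade,
                                make_cornea, to_topography)


def spherical(limbus_angle=gg.DEFAULT_LIMBUS_ANGLE, **kw):
    return make_cornea(gg.default_anterior(), gg.default_posterior(),
                       limbus_angle=limbus_angle, **kw)


def test_rotational_symmetry_of_spherical_cap():
    g = spherical()
    r = np.linspace(0, g.r_max, 30)
    for th in (0.7, 2.0, 4.5):
        assert np.allclose(g.z_ant(r, 0.0), g.z_ant(r, th), atol=1e-15)
        assert np.allclose(g.z_post(r, 0.0), g.z_post(r, th), atol=1e-15)


def test_zero_amplitude_cone_is_identity():
    g0 = spherical()
    g1 = spherical(cone=ConePerturbation(amplitude=0.0, thinning=0.0))
    r = np.linspace(0, g0.r_max, 50)
    th = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    R, T = np.meshgrid(r, th)
    assert np.max(np.abs(g0.z_ant(R, T) - g1.z_ant(R, T))) == 0.0
    assert np.max(np.abs(g0.z_post(R, T) - g1.z_post(R, T))) == 0.0


def test_cone_thinning_minimum_location_and_value():
    cone = ConePerturbation(amplitude=2e-4, r0=1.5e-3, theta0=0.0,
                            sigma=1.5e-3, thinning=0.2)
    g = spherical(cone=cone)
    # oracle: pointwise thickness on a fine polar grid
    r = np.linspace(0, 4e-3, 400)
    th = np.linspace(-np.pi, np.pi, 360, endpoint=False)
    R, T = np.meshgrid(r, th, indexing="ij")
    thk = g.thickness(R, T)
    i, j = np.unravel_index(np.argmin(thk), thk.shape)
    # minimum sits at the cone centre (slightly pulled inward by the sag
    # correction, which thickens the periphery)
    x_min = R[i, j] * np.cos(T[i, j]), R[i, j] * np.sin(T[i, j])
    assert np.hypot(x_min[0] - cone.r0, x_min[1]) < cone.sigma / 2
    # and equals the direct surface evaluation there
    assert thk.min() == pytest.approx(
        float(g.thickness(R[i, j], T[i, j])), rel=1e-14)
    # thinning dominates: min close to cct * (1 - tf) plus the sag correction
    assert thk.min() < g.central_thickness * (1 - cone.thinning) * 1.05


def test_infeasible_thinning_rejected():
    cone = ConePerturbation(amplitude=0.0, thinning=0.95)
    with pytest.raises(GeometryInfeasibleError):
        spherical(cone=cone)


def test_cone_invariants_validated():
    with pytest.raises(ValueError):
        ConePerturbation(amplitude=-1e-5)
    with pytest.raises(ValueError):
        ConePerturbation(amplitude=1e-5, sigma=0.0)
    with pytest.raises(ValueError):
        ConePerturbation(amplitude=1e-5, thinning=1.0)


def test_severity_increases_max_tangential_curvature():
    r = np.linspace(0, 4e-3, 800)
    prev = -np.inf
    for A in (0.0, 2e-5, 6e-5, 1.2e-4):
        g = spherical(cone=ConePerturbation(amplitude=A, thinning=0.1)
                      if A > 0 else None)
        kmax = -np.inf
        for th in np.linspace(0, np.pi, 12, endpoint=False):
            z = g.z_ant(r, th)
            zp = np.gradient(z, r)
            zpp = np.gradient(zp, r)
            kmax = max(kmax, np.max(np.abs(zpp) / (1 + zp**2) ** 1.5))
        assert kmax > prev
        prev = kmax


def test_grade_fixtures_monotone_severity():
    mins = [keratoconus_grade(g).min_thickness() for g in ("G1", "G2", "G3", "G4")]
    assert all(a > b for a, b in zip(mins, mins[1:]))
    with pytest.raises(ValueError):
        keratoconus_grade("G5")


# ---------------------------------------------------------------------------
# topography sampling / refitting
# ---------------------------------------------------------------------------

def test_topography_samples_match_geometry():
    g = keratoconus_grade("G2")
    grid = to_topography(g, 16, 20)
    R, T = np.meshgrid(grid.r, grid.theta, indexing="xy")
    assert np.array_equal(grid.z_ant, g.z_ant(R, T))
    assert np.array_equal(grid.z_post, g.z_post(R, T))
    with pytest.raises(ValueError):
        to_topography(g, 4, 20)


def test_spherical_cap_meridians_identical():
    grid = to_topography(spherical(), 12, 16)
    assert np.allclose(grid.z_ant, grid.z_ant[0][None, :], atol=1e-15)


def test_refit_reproduces_knots():
    g = keratoconus_grade("G3")
    grid = to_topography(g, 16, 24)
    fit = from_topography(grid)
    R, T = np.meshgrid(grid.r, grid.theta, indexing="xy")
    assert np.max(np.abs(fit.z_ant(R, T) - grid.z_ant)) < 1e-12
    assert np.max(np.abs(fit.z_post(R, T) - grid.z_post)) < 1e-12


def test_radial_refinement_reduces_midpoint_error():
    g = spherical()
    errs = []
    for n_rad in (16, 32):
        fit = from_topography(to_topography(g, 16, n_rad))
        r_mid = np.linspace(g.r_max / (2 * n_rad), g.r_max * 0.95, 40)
        errs.append(np.max(np.abs(fit.z_ant(r_mid, 0.3) - g.z_ant(r_mid, 0.3))))
    assert errs[1] <= errs[0] / 2  # cubic interpolation: better than halving


def test_gradient_continuous_across_theta_wrap():
    g = keratoconus_grade("G2")
    fit = from_topography(to_topography(g, 24, 24))
    r = np.array([1e-3, 3e-3, 5e-3])
    h = 1e-7
    left = (fit.z_ant(r, 0.0) - fit.z_ant(r, -h)) / h
    right = (fit.z_ant(r, h) - fit.z_ant(r, 0.0)) / h
    assert np.allclose(left, right, atol=1e-8)


def test_constant_grid_gives_flat_surface():
    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    r = np.linspace(0, 6e-3, 10)
    z = np.full((12, 10), 1.25e-3)
    fit = from_topography(TopographyGrid(theta, r, z, z + 5e-4))
    q = fit.z_ant(np.linspace(0, 6e-3, 33), 1.1)
    assert np.allclose(q, 1.25e-3, atol=1e-12)


def test_nan_fill_lies_between_angular_neighbors():
    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    r = np.linspace(0, 6e-3, 10)
    base = np.sin(theta)[:, None] * 1e-4 + r[None, :] ** 2 / 8e-3
    z = base.copy()
    z[3, 4] = np.nan
    grid = TopographyGrid(theta, r, z, z + 5e-4).fill_missing()
    lo, hi = sorted((base[2, 4], base[4, 4]))
    assert lo <= grid.z_ant[3, 4] <= hi
    # 1-D interpolation oracle: linear between the angular neighbors
    assert grid.z_ant[3, 4] == pytest.approx(0.5 * (base[2, 4] + base[4, 4]),
                                             rel=1e-12)


def test_csv_round_trip(tmp_path):
    g = keratoconus_grade("G1")
    grid = to_topography(g, 12, 16)
    grid.z_ant[5, 7] = np.nan  # missing sample survives serialization
    path = tmp_path / "topo.csv"
    grid.to_csv(path)
    back = TopographyGrid.from_csv(path)
    assert np.allclose(back.theta, grid.theta)
    assert np.allclose(back.r, grid.r)
    assert np.array_equal(np.isnan(back.z_ant), np.isnan(grid.z_ant))
    m = ~np.isnan(grid.z_ant)
    assert np.array_equal(back.z_ant[m], grid.z_ant[m])
    header = path.read_text().splitlines()[0]
    assert header == "theta_rad,r_m,z_ant_m,z_post_m"


def test_nonrectangular_grid_rejected():
    theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    r = np.linspace(0, 5e-3, 6)
    with pytest.raises(ValueError):
        TopographyGrid(theta, r, np.zeros((8, 5)), np.zeros((8, 6)))


def test_biconic_invariants():
    with pytest.raises(ValueError):
        BiconicParams(Rx=-1e-3, Ry=7e-3)
    with pytest.raises(GeometryInfeasibleError):
        make_cornea(gg.default_anterior(),
                    BiconicParams(Rx=6.5e-3, Ry=6.5e-3, offset=0.0))


def test_thickness_floor_everywhere():
    for grade in ("G1", "G4"):
        g = keratoconus_grade(grade)
        assert g.min_thickness() >= 5e-5
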