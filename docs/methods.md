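# Methods

`keratofem` implements a multizone anisotropic hyperelastic finite-element
model of the human cornea and the two inverse iterative procedures that
recover its stress-free configuration from pressurized (topography-derived)
geometry. This note records the model, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Constitutive model

The stroma is a quasi-incompressible fiber-reinforced solid. With the
deformation gradient split `F = J^(1/3) F̄`, `C̄ = F̄ᵀ F̄`, the strain energy
per unit reference volume is

    ψ = ½ k₀ (J − 1)²                                  (volumetric penalty)
      + a₁ (Ī₁ − 3) + a₂ (Ī₂ − 3)                      (Mooney–Rivlin matrix)
      + Σ_families  k₁/(2 k₂) [exp(k₂ (Ī₄ − 1)²) − 1]  (exponential fibers)

with `Ī₄ = m₀·C̄ m₀` and `Ī₆ = n₀·C̄ n₀` the squared isochoric stretches of
the two collagen families. All nine isochoric invariants are computed and
exposed; only Ī₁, Ī₂, Ī₄, Ī₆ enter the energy. The Cauchy stress and the
consistent material tangent are derived analytically in the reference
configuration (S = 2∂ψ/∂C, ℂ = 2∂S/∂C, isochoric projection operators) and
pushed forward; both are verified against 4th-order finite differences of
the scalar energy at every zone parameter set.

Parameters (SI): `a₁ = 40 kPa`, `a₂ = −10 kPa` and `k₂ = 200` are common to
all zones; `k₁` carries the regional fiber density: 50 kPa in the central
disc, the nasal–temporal/superior–inferior sectors and the limbus, 37.5 kPa
in the transition cells, 25 kPa in the oblique cells. The bulk factor is
`k₀ = 5.5 MPa` (configurable); the resulting volume change at physiological
load is |J−1| ≲ 5·10⁻³. The fiber term is implemented exactly as the
energy above — symmetric in (Ī₄ − 1), i.e. stiffening in fiber compression
too; a `tension_only` switch restricts each family to Ī₄ > 1 if the usual
soft-tissue convention is wanted. With `a₂ < 0` the energy loses convexity
at large strain; the solver guards with step halving and reports divergence
rather than silently continuing.

## Multizone segmentation and fibers

The planform is divided into 8 sectors of 45° (half-width 22.5°) centred on
the horizontal and vertical meridians, and rings bounded at diameters 2, 4,
6, 8, 10 and 11 mm measured at mid-thickness; the limbus band runs from
11 mm to the outer boundary (12.5 mm diameter by default). Zone labels:
everything inside 4 mm diameter is the strong central material; the N-T and
S-I sectors keep it out to the limbus; oblique sectors carry the weak
material between 4 and 8 mm and the transition material between 8 and
11 mm; beyond 11 mm is limbus. Ring membership uses half-open intervals
with boundaries assigned outward, octants half-open counterclockwise —
deterministic tie-breaks. Fibers are `m₀ = x̂`, `n₀ = ŷ` in all corneal
zones and a single circumferential family `(−sin θ, cos θ, 0)` in the
limbus (implemented by deactivating the second family's energy term).
Fiber directions are held fixed during all inverse iterations. Depth
dependence of fiber concentration is deliberately not modelled.

## Synthetic corneal fixtures

No patient topographies are available, so study geometries are synthetic:

* **Biconic surfaces** — anterior R = 7.8 mm, posterior R = 6.5 mm, central
  thickness 0.55 mm (standard literature values; fixtures, not claims).
* **Peripheral realism** — raw biconics extended to a 12.5 mm aperture are
  far steeper and thicker than real corneo-limbal anatomy. Beyond 4.5 mm
  radius the surfaces blend C¹-smoothly into a cone whose inclination at
  the outer boundary equals the corneo-scleral interface angle (40° on
  average), and the thickness saturates smoothly at 0.9 mm. Both
  corrections leave the central 9 mm untouched and can be disabled for
  analytic benchmark solids.
* **Keratoconus emulation** — a decentred Gaussian protrusion (amplitude A,
  width σ = 1.5 mm, centre 1.5 mm infero-temporal) on both surfaces plus a
  thinning fraction tf of the local thickness. Severity grades G1–G4 map to
  (A, tf) = (20 µm, 0.10), (40 µm, 0.15), (70 µm, 0.22), (110 µm, 0.30) —
  a monotone fixture convention chosen to span mild-to-severe apical
  thinning, not a clinical calibration.
* **Topography grids** — any geometry can be sampled to a polar
  meridian×radius elevation grid (CSV, NaN for missing samples, missing
  values filled by periodic interpolation along meridians) and refitted by
  periodic cubic splines in θ followed by cubic splines in r. The refit
  reproduces knots exactly and keeps the gradient continuous across the
  θ-wrap.

Because the fixtures are smooth and mildly asymmetric, passing tests show
that the algorithms are implemented correctly and reproduce the *patterns*
reported for patient data (severity amplification, limbus-localized
boundary-condition sensitivity, posterior-limbus strain maxima, sub-micron
EPG agreement between inverse methods). They do not reproduce
patient-specific magnitudes, which depend on measured corneal shape.

## Meshing

Structured, zone-conforming hexahedral meshes: a butterfly/O-grid core
(square rotated 22.5° so both its corners and all sector boundaries are
mesh lines), a transition band onto the 2 mm circle, then annular rings
whose boundaries coincide with the segmentation circles. Node columns are
anchored at the mid-surface on those exact circles and run along the local
mid-surface normal (vertical columns are available for analytic benchmark
checks); column ends are located exactly on the two surfaces and layers are
spaced equally along each column. The rim columns therefore form the
corneo-scleral cut cone perpendicular to the 40°-inclined interface. With
L layers, core size ns = 2a, nt transition divisions and radial divisions
rᵢ per band, the element count is L·(ns² + 4·ns·nt + 8·a·Σᵢ rᵢ), verified
against explicit enumeration. All Jacobians are checked positive at the
2×2×2 Gauss points.

The canonical study resolution (`default_study_spec()`) is 4 layers, a = 2
and a doubly divided limbus band (576 elements): the limbus band is where
the clamped-edge boundary layer lives, and resolving it is what places the
strain maximum there. Desk-scale meshes are deliberately smaller than
clinical meshes; the count formula and convergence test (apex displacement
changes < 2 % under uniform ×2 refinement) justify the choice.

## Forward solver

Total-Lagrangian assembly on trilinear hexahedra with selective reduced
integration: deviatoric stress and tangent at the 8 Gauss points, the
volumetric penalty at the element centroid (mean-dilatation family of
locking control). The IOP (converted at 133.322 Pa/mmHg) is a follower
load on the posterior facets using the exact bilinear-quad vector area
½(d₁×d₂), with the analytic load stiffness in the (unsymmetric) tangent.
Loading is incremental — 10 equal substeps by default — with full Newton
per substep (relative residual tolerance 10⁻⁸, max 30 iterations, step
halving on element inversion, an extrapolation predictor between substeps,
and an absolute force floor so zero-load states converge exactly).

Boundary conditions are multipoint constraints by master–slave elimination
`u = T q`, which satisfies the constraints exactly:

* **embedded** — all rim degrees of freedom removed (fully clamped);
* **pivoting** — each rim cross-section (one node column through the
  thickness) moves rigidly with a single rotation angle about the local
  circumferential tangent through the section's mid-thickness centroid;
  translations and the other two rotations are blocked. The rotation is
  linearized about the reference configuration, adequate for the
  milliradian rotations at physiological load.

Pivoting admits every embedded-admissible state plus the rim rotations, so
it is the softer constraint; numerically this shows as larger external
work of the pressure (the apex displacement itself may be smaller because
rim rotation relieves the bending boundary layer — the compliance
inequality is the one verified).

A prestress deformation gradient `F_pre` may be supplied per Gauss point;
the law is evaluated at `F_total = F_inc(u)·F_pre` and the effective
first Piola–Kirchhoff stress `J_pre⁻¹ (F_total S) F_preᵀ` is integrated
against the reference gradients, so equilibrium is exact in the current
configuration. `F_pre` is ramped linearly with the load factor across
substeps.

The solver is verified against a 1-D semi-analytic oracle: incompressible
Mooney–Rivlin inflation of a thick spherical shell,
`P = ∫ Ŵ′(λ)/(λ³−1) dλ` (quadrature + bracketed inversion on the ascending
branch of the limit-point curve), meshed here as an equiangular cubed
sphere. At k₀/µ ≈ 90 the quasi-incompressible FEM and the incompressible
limit differ by far less than the 2 % verification band.

## Inverse stress-free-geometry recovery

Both methods monitor 57 control nodes per surface (apex + 8 sector
meridians × 7 circles, on both the anterior and posterior surfaces) and
converge when the maximum norm of the coordinate difference (displacements
method) or the maximum control displacement (prestress method) drops below
ε = 10⁻⁹ m.

* **Displacements method** — fixed-point update of the reference geometry,
  `X ← X − (x(X) − X_measured)`, starting from the measurement. No
  relaxation by default; an under-relaxation factor is available if a
  geometry ever makes the map non-contractive.
* **Prestress method** — the geometry stays at the measurement while the
  incremental deformation gradient is composed into the prestress,
  `F_pre ← F_inc·F_pre` (prestress first in the multiplicative history).
  The converged Gauss-point stresses are the physiological field; the SFG
  is exposed afterwards by relaxing the prestressed model at zero IOP.
  This extra step applies the stress field without re-updating it through
  the anisotropic law, so re-pressurizing that SFG reproduces the
  measurement only approximately (bounded by 10 µm on fixtures and logged),
  while the two methods' estimated physiological geometries agree to
  sub-micron maxima.

On the synthetic fixtures both methods converge in ~9–12 iterations,
consistent in order with the 12–16 reported for patient geometries.

## Post-processing

Von Mises stress is √(3/2 dev σ:dev σ). A "von Mises" equivalent strain is
not uniquely defined; the implementation uses the common FE-postprocessor
convention — the deviatoric intensity of the logarithmic (Hencky) strain
scaled by 1/(1+ν_eff) with ν_eff = 0.5 — so a uniaxial incompressible state
diag(e, −e/2, −e/2) reports e. Fields export to legacy-ASCII VTK
(hand-written writer/reader pair, round-trip tested bit-exactly); summaries
are emitted in SI plus micrometers for comparability with clinical tables.
The whole pipeline is deterministic: repeated runs from one configuration
produce byte-identical summary JSON, independent of BLAS thread count.

## Known limitations

* Fixtures are smooth surrogates; no claim of geometric equivalence with
  any keratoconus grade is made or testable without deposited topographies.
* 8-node SRI hexahedra replace 20-node mixed u-P elements; the locking
  contract is verified on the shell oracle, but very coarse meshes remain
  stiffer than quadratic elements would be.
* The pivoting constraint is linearized about the reference configuration
  (exact for the verification criterion; finite-rotation rims would need
  an updated constraint).
* Viscoelasticity, fiber dispersion, depth-dependent stiffness, aqueous
  humor and whole-globe coupling are out of scope.
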