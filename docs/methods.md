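# Methods

## The model

`dccsim` simulates the mechanics of a swollen brain inside a rigid skull
and the tissue herniation that follows a decompressive craniectomy (DCC),
the surgical removal of a skull patch to relieve intracranial hypertension.

The brain is a biphasic (poroelastic) continuum: a hyperelastic solid
skeleton (cells and extracellular matrix) saturated by interstitial fluid.
Post-traumatic edema is modelled as isotropic volumetric growth through the
multiplicative decomposition of the deformation gradient,

    F = Fe Fg,        Fg = λg I,

so a growth stretch λg ≥ 1 swells the tissue without generating stress by
itself; only the elastic part Fe is loaded. The solid follows a modified
neo-Hookean strain energy

    W = ½ [ μ (Ī₁ − 3) + K (Je − 1)² ],

with Je = det Fe, Ī₁ = Je^(−2/3) tr(FeᵀFe) (the isochoric first invariant,
so the μ-term is purely deviatoric), giving the Cauchy stress

    σs = μ Je^(−5/3) dev(be) + K (Je − 1) I,     be = Fe Feᵀ.

The fluid contributes σf = −p_i I (positive interstitial pressure p_i loads
the solid compressively — the standard poromechanics sign; the total-stress
balance is ∇·(σs + σf) = 0). Fluid moves by Darcy's law,
φf (v_f − v_s) = −k ∇p_i, and exchanges volume with the microvasculature
and lymphatics through Starling's approximation

    Q = Lp (S/V)(p_v − p_i) − Lpl (Sl/Vl)(p_i − p_l).

Eliminating the fluid mass balance yields the pressure equation
−k ∇²p_i = Q − ∇·v_s. The default mode is stationary (v_s = 0): DCC
outcomes are modelled at equilibrium. A quasistatic mode (backward-Euler
v_s = Δu/Δt) exists for transient studies but is not used by the planning
pipeline. Viscoelasticity is deliberately ignored: over the minutes-to-hours
timescale of a craniectomy the elastic response dominates.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| μ | tissue shear modulus | 10 × 10³ | Pa |
| K | tissue bulk modulus | 30 × 10³ | Pa |
| k | tissue hydraulic conductivity | 6.7 × 10⁻¹² | m² Pa⁻¹ s⁻¹ |
| Lp, S/V, p_v | vascular wall conductivity, density, pressure | 2.7 × 10⁻¹², 7000, 4 × 10³ | m Pa⁻¹ s⁻¹, m⁻¹, Pa |
| Lpl, Sl/Vl, p_l | lymphatic counterparts | 3.75 × 10⁻⁴, 7000, 0 | same |
| λg | growth stretch (10% swelling = 1.1) | 1 → 1.1 | – |

Wall conductivities are carried in m Pa⁻¹ s⁻¹ (the Starling dimension that
makes Q a volumetric rate, 1/s); magnitudes are the published physiological
values. λg is interpreted as a *linear* stretch by default (λg = 1.1 means
Jg = 1.331); a `volumetric` interpretation flag on `GrowthField` treats λg
as the volume ratio instead (linear stretch λg^(1/3)).

With these defaults the Starling reaction dominates diffusion: the pressure
boundary-layer width √(k/(LpS/V + LplSl/Vl)) is ≈1.6 µm, so at stationarity
p_i sits at its equilibrium root p∞ ≈ 2.9 × 10⁻⁵ Pa everywhere except
unresolvable layers at drained boundaries. Reaction-dominated problems are
not oscillatory, so no stabilization is used; verification problems rescale
Lpl so the layer (αR of a few) is mesh-resolvable.

## Geometry and meshing

The skull cavity is an idealized ellipsoid (default semi-axes
80 × 66 × 59 mm, ≈1.3 l — adult scale); subject-specific meshes can be
supplied in Gmsh MSH 4.1, VTU or XDMF instead. Coordinates: origin at the
centroid, x = left–right (left hemisphere at x > 0), y posterior–anterior,
z inferior–superior; geometry in mm, solver in SI.

Craniectomy openings are cavity-surface patches cut by cones about an
opening axis: circular (unilateral, radius r so that the planar disc area
is the clinically quoted πr²), elliptical (bifrontal, two angular
half-widths), optionally excluding a mid-sagittal bar strip. Bifrontal
extents are found by a 1D root-find so the curved patch area matches a
requested area within 1%. The mesher builds a layered-icosphere ball
(angular subdivisions × radial shells), maps it radially onto the
ellipsoid, and snaps the nearer endpoint of every rim-crossing surface edge
onto the opening rim, so the tagged patch is the polygon inscribed in the
rim; a facet belongs to the opening iff all three of its vertices are
inside or on the rim. Hemisphere region tags split cells at x = 0.

## Discretization and solver

Mixed Taylor–Hood-style pair on tetrahedra: quadratic Lagrange
displacement, linear Lagrange pressure, isoparametric quadratic geometry
(boundary midside nodes snapped onto the curved surface), and a 27-point
conical-product Gauss rule (exact to total degree 5). The momentum residual
is assembled in the reference configuration through the first Piola
transform P = J σ_tot F⁻ᵀ; the pressure operator is pulled back by
J F⁻¹ k F⁻ᵀ and the Starling source weighted by J.

The Newton linearization is exact: stationary-mode tangents use the closed
form that follows from P = c₁F + c₃F⁻ᵀ for this material, and are verified
in the test suite against a complex-step differentiation of the residual
(machine-precision agreement); the complex-step path is also what the
quasistatic mode uses. Growth is ramped incrementally (default 10 load
steps to the target, proportional per-region scaling), each level solved by
Newton with a backtracking line search (halving, at most 8 halvings) on the
free-dof residual norm; convergence at 10⁻⁸ relative residual reduction
(10⁻¹⁰ absolute floor). Linear systems go to SuperLU after symmetric Jacobi
equilibration — the momentum and fluid blocks differ by ~16 orders of
magnitude in natural units, and equilibration keeps the factorization
well-scaled. Everything is deterministic; the `seed` option exists for
future randomized components and changes nothing today.

The initial pressure guess defaults to p∞ (the field's stationary value
away from drains), which makes the sealed closed-skull calibration converge
at the first residual check — the homogeneous confined state u = 0 is the
exact discrete solution there. An element inversion (det F ≤ 0) during
assembly names the offending cell and suggests more load steps.

## The two-step DCC procedure

1. **Closed-skull step** — every boundary facet fixed (u = 0), zero fluid
   flux; λg ramped 1 → target. The volume-averaged ICP loading is recorded
   per level. Two estimators exist: `avg_total_pressure`
   (mean of −tr(σ_tot)/3; the default) and `avg_fluid_pressure` (mean p_i).
   At stationarity with physiological drainage p_i ≈ p∞ ≈ 0, so only the
   total-pressure estimator carries loading information; in a rigid fully
   fixed cavity it equals K(1 − λg⁻³) — geometry-independent
   (55.96 mm-Hg at λg = 1.1, using 133.322 Pa per mm-Hg). ICP loading is
   reported relative to the λg = 1 baseline and is the increment *above*
   physiological ICP (7–15 mm-Hg).
2. **Open-skull step** — the same mesh with opening facets traction-free
   and drained (p_i = 0); the swollen tissue bulges through the opening.
   Herniated volume, stress and displacement extrema, and midline shift are
   extracted per level.

A `PlanningCurve` pairs each level's closed-skull ICP loading (x) with the
open-skull outcomes (y). The closed-skull step always runs on the sealed
mesh, so the calibration is independent of the opening specification.

## Outcome measures

- **Herniated volume**: primary estimator ∫(det F − 1) dV₀ over the
  reference brain; secondary estimator, the change of the volume enclosed
  by the deformed boundary, integrated exactly over the curved quadratic
  surface (degree-5 triangle rule). The two are identical by the divergence
  theorem; their discrete difference is a bookkeeping check and >2%
  disagreement warns.
- **Midline shift**: no falx exists as a material, so the proxy is the set
  of P2 nodes within half an element size of the mid-sagittal plane; the
  shift is the sagittal-normal displacement component of largest magnitude
  there (signed; positive toward the left hemisphere, x > 0).
- **Stress extrema**: principal Cauchy stresses of the solid phase at
  quadrature points; "max compressive stress" is the magnitude of the most
  negative principal value. Because the raw maximum sits at the reentrant
  craniectomy edge and can grow under refinement, volume-weighted 99th/95th
  percentiles are reported alongside as the mesh-stable summary.
- **Field exports**: VTU with displacement in cm, p_i in mm-Hg, minimum
  principal stress in kPa (clinical figure units).

## What the synthetic geometry does and does not show

The built-in ellipsoid preserves the model physics — confinement, growth
loading, drainage, opening mechanics — and reproduces the
geometry-independent quantities exactly (confined ICP–λg calibration,
constitutive behavior). It does not reproduce subject-specific anatomy:
gyri/sulci, ventricles, the falx, or a subject-specific MR-derived mesh.
Quantities tied to that anatomy (absolute midline shifts, peak stresses at
specific sites) are therefore checked as *orderings and ratios* on the
synthetic head, not as absolute values. On sweep-resolution meshes
(~3–4k tets) the implemented model gives, at λg = 1.1 with a r = 40 mm
unilateral opening: herniated volume ≈ 33 ml, peak displacement ≈ 10 mm,
peak compressive stress ≈ 16 kPa — the clinically reported magnitudes.

One pattern reported in the clinical modelling literature does **not**
emerge here: peak compressive stress approximately doubling with each
doubling of μ at fixed swelling. With the
bulk modulus held fixed, the confined driving stress K(1 − λg⁻³) is
μ-independent and the deformation scales roughly as 1/μ, so μ × strain
saturates; equivalently, peak displacement is *not* μ-independent here (it
varies ≈2× from μ = 5 to 20 kPa, which is also what makes the herniated
volume decrease with stiffness). The corresponding acceptance test asserts
the published pattern and fails; the package reports what the stated
equations and parameters produce.

## Numerical and design choices

- Problem sizes: routine pipeline meshes are ~2–5k tetrahedra
  (h ≈ 16–20 mm), where a sparse LU is a few seconds; verification meshes
  go to ~60k tetrahedra where the solve is pressure-only. These sizes give
  discretization errors well inside the tolerances being tested (volume
  bookkeeping <1%, sphere-oracle L2 <1% at αR = 5).
- Load-step invariance, determinism (bit-identical convergence logs), the
  patch test (prescribed affine boundary reproduced to machine precision)
  and the oedometer small-strain limit are all asserted in the test suite.
- Degenerate inputs: λg < 1 (resorption) is rejected; meshes without fixed
  facets are rejected (rigid-body motion); a mesh whose element size does
  not resolve the smallest opening is rejected at meshing time.
- Open questions resolved as package policy: the fluid-stress sign is
  σf = −p_i I (compressive loading); λg is a linear stretch by default with
  a volumetric flag; the closed-skull step seals the same mesh rather than
  meshing a separate closed geometry; both ICP estimators are always
  computed and reported.

## Known limitations

Homogeneous isotropic tissue (no gray/white distinction, no dura, falx or
tentorium as materials); rigid skull without thickness; no contact at the
craniectomy edge (tissue may slide through the rim unhindered); equilibrium
only — the transient ICP evolution after opening is out of scope; no
image-derived geometry pipeline (external labeled meshes can be read
instead).
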