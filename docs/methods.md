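# Methods

`symphysim` analyses the mechanical environment of the pubic symphysis during
single-leg stance: density-mapped elastoplastic bone, a Mooney–Rivlin
interpubic disc, Hill-type static optimization of muscle redundancy, and a
small incremental finite-element solver, all exercised on a synthetic
pelvis-like geometry so the pipeline runs with no subject data. Units are a
consistent mm–N–MPa–g/cm³ system throughout.

## Bone constitutive model

Bone is isotropic, inhomogeneous and elastoplastic. Per element, the apparent
density ρ (g/cm³) is obtained from the CT calibration density by the affine
map ρ = 1.54·ρ_CT + 0.0784 and drives power laws for the elastic modulus
(E = 2065·ρ³·⁰⁹ compact, 1904·ρ¹·⁶⁴ cancellous, ν = 0.3 for both), the yield
stress (σ_y = 57.75·ρ¹·⁷³ for ρ ≥ 0.945, 76.5·ρ⁶·⁷ below; the branches
intersect within 0.1 MPa of the threshold), and the post-yield degradation
parameters σ_min = 8.5·ρ³·⁶⁸, E_p = −244·ρ²·², ε_ab = 0.258·ρ − 0.07.

The uniaxial curve is piecewise linear: elastic rise to (σ_y/E, σ_y), a
perfectly plastic plateau to ε_ab (no hardening law is available, so the
ultimate strength is taken equal to σ_y), linear softening with slope E_p down
to σ_min, constant σ_min beyond. Two corners of the printed laws require
decisions:

* **ε_bc.** The printed end-of-softening expression |(σ_y − σ_min)/E_p + ε_ab|
  evaluates *below* ε_ab for plausible densities (a sign issue in the source);
  it is computed and reported verbatim by `softening_params` but the curve
  terminus is derived from (σ_y − σ_min)/|E_p| instead, which produces the
  expected elastic/plateau/softening shape.
* **Low densities.** Below ρ ≈ 0.483 the residual-stress law overtakes the
  cancellous yield law (σ_min ≥ σ_y), leaving nothing to soften to; such
  densities are modelled elastic–perfectly-plastic at σ_y. Below ρ ≈ 0.2713
  the softening-onset strain is non-positive and `softening_params` raises a
  degenerate-material error; the FE material table keeps those elements
  elastic. Densities are floored at 0.05 g/cm³ for numerical robustness.

Tissue classification (compact vs. cancellous) uses the same 0.945 g/cm³
threshold as the yield branch, so one threshold governs both laws.

## Interpubic disc

The disc is a three-parameter Mooney–Rivlin material,
W = C10(I1−3) + C01(I2−3) + C11(I1−3)(I2−3) with C10 = 0.1, C01 = 0.45,
C11 = 0.6 MPa. The closed-form incompressible uniaxial Cauchy stress
σ = 2(λ² − 1/λ)(∂W/∂I1 + ∂W/∂I2/λ) is implemented for verification and is
checked against a central-difference derivative of W along the uniaxial path
(agreement ≲ 1e−10 relative). The small-deformation solver uses the
consistent near-incompressible linearization E = 2G(1+ν), G = 2(C10+C01) =
1.1 MPa, ν = 0.475 — a single-element-technology choice (linear tetrahedra
everywhere) in place of the hybrid hexahedra a large-strain treatment would
need. Reported disc strains on the toy geometry reach ~0.3, so disc stresses
from the linearized law are indicative, not hyperelastically exact; the
Mooney–Rivlin law itself is retained and tested in `materials`.

## Muscle forces

Each actuator follows a Hill-type form F = a·F0·f_L(L/L_opt)·f_v(v)·cos α
with a rigid tendon. The force–length factor is the standard Gaussian
exp(−((L/L_opt − 1)/0.45)²); the force–velocity factor is a saturating
hyperbola with f_v(0) = 1 (irrelevant in static analyses, where v = 0). Both
are injectable per problem. Static optimization minimizes Σa_i² subject to
joint-moment balance Σ a_i F_i^max r_ij = Q_j and bounds 0.01 ≤ a_i ≤ 1; the
absolute value in the moment sum is inert because activations and force
factors are non-negative. The QP (diagonal Hessian, equalities, box) is
solved by an exact active-set scheme with a KKT check; infeasible targets
raise an error carrying the minimal-residual bounded least-squares solution
(so a single muscle asked for zero moment reports the lower bound a = 0.01).
A packaged 27-muscle single-leg-stance force table (with zero rows preserved
and the source's typesetting artifacts flagged, e.g. "13.I" read as 13.1) is
used directly as nodal loads when the optimization stage is bypassed.

## Finite-element solver

Linear (constant-strain) tetrahedra; assembly is vectorized over elements.
Boundary conditions follow the reference loading scheme: the left sacroiliac patch is
fully fixed; the right one carries grounded springs whose **total** stiffness
per translational axis is k = 4285 N/mm, distributed equally over the patch
nodes (the source gives one scalar; acting on all three axes is the default).
Bone–disc interfaces are tied: each slave node's displacement equals the
barycentric interpolation of its master facet (transmits tension and
compression); the reduction is a sparse transformation u = T·q. Reference-
point forces are spread by distributed couplings whose nodal forces reproduce
the resultant exactly and have zero resultant moment about the reference
point (weighted-inertia correction).

Loading is incremental: first 5% of the total load, then steps of at most 10%
(the source's "increment sizes" are read as load-factor fractions — as
printed they carry length units, which no static load-stepping scheme uses).
Within each increment the bone nonlinearity is resolved by secant-modulus
iteration: the von-Mises-equivalent strain ε_eff = 3/(2(1+ν))·√(2/3 e′:e′)
(scaled so σ = E·ε_eff holds in uniaxial stress) is looked up in the
element's uniaxial curve and E_sec = σ(ε_eff)/ε_eff, with full updates while
the residual decreases and 0.5 relaxation otherwise, warm-started across
increments by proportional strain extrapolation. Convergence requires the
global equilibrium residual with the *updated* moduli below 1e−6 relative.
After the last increment one linear solve with the converged moduli realigns
the stored state, so support reactions balance applied loads to machine
precision. Secant iteration trades the quadratic convergence of return
mapping for robustness and transparency at desk scale; it yields the same
converged state for proportional monotonic loading, which is the only regime
exercised here.

Verification: an affine patch test passes to ~1e−13; a slender cantilever
(aspect ratio 10, 80×12×12 cells) reproduces the Euler–Bernoulli tip
deflection within ~4% (linear tetrahedra converge slowly in bending — the
mesh was chosen from the convergence sequence 8.9% → 6.1% → 3.9%); tied
twin blocks match the merged-mesh solve to 1e−6; elastic problems reproduce
the one-shot linear solution independent of increments.

## Synthetic pelvis

The generator emulates the structures the analysis needs, not pelvic anatomy:
two mirror-symmetric bone bodies — a superior-ramus-like bar (60 mm long,
40×24 mm cross-section, bent 0.6 rad posteriorly) plus an iliac-wing plate
(45 mm tall over the outer 30% of the arm, carrying the gluteal attachments)
— joined by a slit-like disc block (4 mm gap) tied to the bone faces. Meshes
are structured Freudenthal tetrahedra, graded from 1.5 mm at the symphysis to
the 5 mm global bone size (≈20k elements at defaults, within the 50k budget).
The density field assigns a cortical calibration level (ρ_CT = 1.1, mapping
to ρ ≈ 1.77, compact branch) to elements within 3 mm of the bone surface and
a cancellous level (ρ_CT = 0.25 → ρ ≈ 0.46, cancellous branch) to the core,
plus seeded Gaussian noise (sd 0.02 g/cm³, truncated at zero), so both
constitutive branches and the plastic plateau are exercised under the
reference loads. Everything is deterministic under a fixed seed.

The 27 muscle attachment sites are stationed by rough anatomical aspect
(adductor group near the symphysis on the inferior face, iliopsoas and
anterior thigh muscles mid-arm, gluteals on the wing), and the default force
directions run from each attachment toward an anatomical insertion point
(greater/lesser trochanter, medial femoral shaft, knee region) anchored to
the femoral-head point below the acetabular patch; all targets are
overridable, since only force magnitudes are tabulated. Two reference load
cases are packaged: (1) the hip-joint reaction (852, 2052, −1042) N at the
acetabular reference point; (2) the same plus the tabulated muscle forces.
The component-to-axis mapping (F1→x lateral, F2→y vertical, F3→z posterior)
is a convention choice and is configurable.

**What the toy does and does not show.** It exercises every pipeline stage
under realistic magnitudes, checks equilibrium, branch coverage, determinism
and the solver's verification problems. It does *not* reproduce the closed
ring of the real pelvis (two rami + ischium per side), and consequently the
published qualitative ordering between the two load cases (hip bones more
stressed under the reaction, symphysis more stressed under muscle loading)
does **not** emerge: both quantities land within ±2% between cases. In the
two-body topology the hip-bone maximum sits near the acetabular load, which
is common to both cases, and the symphysis sees offsetting muscle effects
(vertical-shear cancellation vs. added lateral tension). The ordering test
in the acceptance suite asserts the reported ordering and fails on this
geometry; absolute reported field values (e.g. 86.50 MPa) depend on the
subject's geometry and are out of reach by design — the packaged checks for
them are the printed-input arithmetic (reaction-magnitude composition,
percent-difference computation) plus the property-based verification above.

## Postprocessing

Reduced stress is the von Mises invariant; strains are logarithmic principal
strains, eigenvalues of ½·ln(FᵀF) with F = I + ∇u (guarded against inverted
elements). Summaries report per-part maxima of σ_red and ‖u‖ and the extreme
log strains, plus a 99th-percentile σ_red as a guard statistic against
single-element concentrations at constrained or loaded nodes; maxima remain
the headline values. Case comparisons always record their base explicitly
(the reported 14.8% uses the reaction-only value as base).

## Numerical choices and limitations

Tie projection tolerance 1 mm; equilibrium tolerance 1e−6 relative per
increment; secant cap 40 iterations per increment with non-convergence
reported with the last residual and load factor. Small-strain kinematics
with log-strain postprocessing is inconsistent at the disc's strain levels
(~0.3) — acceptable for load-path comparisons, not for hyperelastic stress
accuracy. No unilateral contact (interfaces are glued), no anisotropy or
viscoelasticity, no damage accumulation, single static snapshot (t = 0.74 s
of gait) only. Mesh I/O covers a deliberately small subset of each format
(MSH 2.2 tets + physical names; legacy VTK; INP nodes/C3D4/NSET/ELSET/
SURFACE) — enough for round trips of everything the pipeline produces.
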