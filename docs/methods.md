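# Methods

This note documents the models, numerical choices and scope of `palpquant`:
what is simulated, how, with which defaults, and what passing tests do and
do not demonstrate.

## Physical model and assumptions

The tissue sample is a rectangular 2D section `[0, width] × [0, height]`
(x along the palpated top surface, y positive downward; all lengths in mm).
It is modeled as an isotropic, incompressible, hyperelastic solid in
**plane strain**: the 2D section is the cross-section of a long block, and
all forces are per unit out-of-plane thickness (N/mm). Plane strain was
chosen over plane stress because the palpated blocks are wide compared to
the indenter and, more importantly, only *relative* and *derivative*
quantities of the force profile enter the inversion, which is calibrated
and inverted with the same 2D model. Absolute 2D forces are therefore not
comparable to 3D experimental forces; the pipeline never relies on them
being so.

The material response is quasi-static and elastic. Real soft tissue and
gelatin are viscoelastic; the elastic idealization corresponds to an
experimental protocol with a slow indentation rate and a long relaxation
wait at each probe point, and is the main modeling limitation (see below).

Constitutive models (stress-like quantities in MPa):

* **Ogden** (order 2 by default, Abaqus normalization on isochoric
  principal stretches), with the conventional “−3” in the deviatoric sum so
  that the energy vanishes in the reference configuration. Initial shear
  modulus μ₀ = Σμᵢ, Young's modulus E = 3μ₀ at ν = ½ exactly.
  Package defaults for prostate-mimicking tissue:
  healthy μ = (0.02119, −0.01120) MPa, α = (2.244, −1.081) (E ≈ 30 kPa at
  small strain; the parameters were fitted over a large strain range
  against a 20 kPa target and are taken as given, not re-derived);
  cancerous tissue has exactly twice the μᵢ (2:1 modulus ratio).
* **Neo-Hookean** Ψ = C₁(Ī − 3), E = 6C₁, used for the gelatin phantoms
  (healthy C₁ = 4.6898·10⁻³ MPa → 28.1 kPa, cancerous 6.5872·10⁻³ MPa →
  39.5 kPa). Internally it is run through the Ogden machinery as
  μ = 2C₁, α = 2, to which it is algebraically identical.

Both tissues are treated as fully incompressible at the constitutive level;
the volumetric D-coefficients are exposed but default to empty.

## Finite-element forward model

* **Mesh**: structured grid of quadrilateral cells, each split into four
  linear triangles through the cell center (“crossed” pattern). This
  pattern is used because plain linear triangles lock badly under
  near-incompressibility while the crossed arrangement does not, at the
  cost of more elements. `mesh_size` sets the cell edge; an optional
  vertical `grading` coarsens rows geometrically toward the (fixed) bottom.
  Elements are labeled healthy / cancerous / interface-mixture from the
  exact (shapely-clipped) overlap of each triangle with the nodule regions;
  the per-element cancer area fraction blends the material linearly in μᵢ
  (for the diffuse-interface scenario, the shell's 50/50 mixture modulus is
  the arithmetic mean of the two tissues).
* **Incompressibility**: volumetric penalty U(J) = κ/2 (J−1)² with
  κ = `kappa_ratio`·μ₀ per element. The default `kappa_ratio = 100`
  corresponds to ν ≈ 0.495, inside the 0.49–0.5 range reported for
  prostate tissue. Ratios of 1000 (ν ≈ 0.4995) are supported and give
  forces a few percent stiffer but cost several times more Newton
  iterations; 100 was adopted as the default accuracy/robustness
  compromise. Forces scale exactly linearly in a global modulus factor
  because κ is tied to μ₀.
* **Kinematics and solution**: total Lagrangian; the deformation gradient
  is constant per triangle; principal stretches come from the closed-form
  eigenvalues of C = FᵀF, and the second Piola–Kirchhoff stress is
  assembled isotropically as S = aI + bC (no eigenvectors needed). The
  consistent tangent is a central finite difference of the first
  Piola–Kirchhoff stress with step 10⁻⁶ (tangent error ~10⁻⁹, so Newton
  convergence is unimpaired while avoiding an error-prone analytic
  spectral tangent). Newton iterations use LU reuse while the residual
  contracts fast, refreshing the tangent otherwise, plus a backtracking
  line search (the stiff volumetric penalty otherwise causes overshoot).
  Convergence requires a relative residual below 10⁻⁸ at every increment.
* **Contact**: the probe is the rigid circular cross-section (radius 5 mm)
  of a 10-mm spherical-tipped indenter, frictionless. The default mode
  (“prescribed”) drives the vertical displacement of top-surface nodes
  inside the geometric overlap onto the indenter arc, leaving horizontal
  dofs free (frictionless), with an **active-set** iteration: nodes whose
  reaction turns adhesive are released, penetrating nodes are re-added.
  Without the active set the scheme converges to a “glued” solution with
  spurious edge adhesion — releasing it restores the unilateral contact
  solution and closes the work–energy balance to <0.1%. The alternative
  “penalty” mode applies radial penalty forces against the analytic circle
  (auto stiffness 1000·μ₀ per node, penetration well under 1% of the
  indentation depth); the two modes agree within ~3% at 2-mm meshes and
  converge toward each other under refinement (~0.8% at 1.5 mm).
* **Loading**: displacement-controlled quasi-static ramp.
  `protocol.increments` (default 10) is the number of load steps at the
  largest protocol depth; shallower depths use proportionally fewer
  (minimum 2) and the solver bisects an increment automatically if Newton
  fails. Because the model is elastic, the state at a given depth is path
  independent; a sweep therefore records the forces at all requested
  depths along a single ramp per position, which is exact and ~3× cheaper
  than separate solves. Probe points remain mutually independent
  (each starts from the undeformed configuration), matching a measurement
  protocol with full relaxation between probings.

Verified mechanical invariants (test suite): mirror symmetry of profiles to
machine precision; zero horizontal reaction; force superlinearity in depth;
exact force doubling under modulus doubling; external work equal to stored
energy within 1%; agreement with a small-strain linear-elastic solve within
3% at 0.1-mm depth; peak-force change under 2× mesh refinement below 2%
(2 mm → 1 mm).

## Profile analysis

The second derivative of force with respect to probe position is taken from
a cubic smoothing spline fitted over **all** points of a profile;
`smoothing="auto"` selects the parameter by generalized cross-validation
(scipy's `make_smoothing_spline`), `smoothing=0` gives the interpolating
spline (exact for polynomial profiles). The smoother is linear in the
forces at a fixed parameter, and GCV is scale-invariant, so curvature
scales linearly with force. Values within one indenter radius of the
profile ends are flagged unreliable and excluded from inversion.

Localization returns the position maximizing |F − F_baseline| against a
healthy-background profile, with ties broken toward the scan center and a
noise floor of 3× the robust spread of the baseline's own spline residuals
(below it, “no nodule detected” is signaled).

One empirical observation: the homogeneous block's force profile is itself
domed (traction-free lateral edges soften the ends), so its curvature at
interior positions is not negligible — about 0.3× the curvature measured
above a 16-mm nodule at 30-mm depth in the 100×100-mm configuration. The
nodule contrast is a solid factor (>2×), not orders of magnitude; the
inversion is unaffected because the same background is baked into the
calibration library.

## Calibration library and inversion

`build_library` runs the forward model for circular nodules over an
ascending (center-depth × diameter) grid, at every protocol indentation
depth, storing the profile curvature at the nodule position (the library
nodule is centered under the probed line's midline; by symmetry the
library is translation-invariant, and lateral position is handled by
localization). Symmetric probe grids are mirrored about the nodule,
halving the forward solves exactly.

Depth convention: circle depths refer to the **center**; phantoms specified
by top-face depth are converted via `depth_center = depth_top + extent/2`.

`invert_to_curve` inverts one measured curvature along the diameter axis by
shape-preserving (PCHIP) interpolation per tabulated depth — monotonicity
in diameter is what makes this well posed, and it holds at the indentation
depths the inversion relies on (5 and 10 mm); at 1-mm indentation and for
the deepest nodules the signal approaches the background level and a
monotone-branch linear fallback is used. Depths where the measurement is
out of range are omitted; all-out-of-range raises an explicit
“outside calibrated envelope” signal.

`intersect_curves` joins curve points linearly between tabulated depths and
minimizes the sum of squared distances from a trial point to all curves in
coordinates normalized by the depth and diameter spans (so both axes
contribute comparably). Local minima of a 121×121 grid scan are polished
by Nelder–Mead; candidates within 10% relative residual of the best are all
reported (measurements frequently admit two near-solutions), the best is
chosen, and a configurable residual ceiling (default 0.5 in normalized
units) triggers an “inconsistent measurements” failure. When the
measurement is generated by the same forward model with the truth on the
library grid, every curve passes through the truth exactly and the
recovered point has residual < 10⁻⁶.

## Synthetic phantoms

`standard_configurations()` provides ready-made bundles: the 100×100-mm
in-silico block (40 probe positions inset one indenter radius from the
edges, indentation depths 1/5/10 mm), the irregular-nodule scenarios
(intersecting circles of 10 & 15 mm — center offset 6.25 mm, the mean
radius, chosen so they genuinely intersect; a fixed synthetic stand-in
polygon of ~15-mm extent for the “arbitrary shape” case; a 20/30-mm
diffuse annulus; a 25×12.5-mm rectangle) and the 2D mid-section of a
gelatin phantom (100×31 mm, 20×12-mm rectangular nodule with its top face
10 mm below the surface, probed at 5 positions spaced 20 mm with depths
2/4/6 mm, neo-Hookean 28.1/39.5 kPa).

`synth_measurement` perturbs a forward sweep with (i) a per-probing
contact-finding error: a zero-mean Gaussian indentation-depth offset
(clipped at ±0.5 mm) applied by re-evaluating the local force–depth curve
(monotone PCHIP through the origin) at depth + offset, and (ii) zero-mean
Gaussian force noise scaled to the per-profile maximum. Both are
reproducible from a seed.

What the generator emulates: probe-force measurement with independent
probings, additive sensor noise, and the contact-point-finding uncertainty
that degrades shallow indentations. What it does **not** emulate:
viscoelastic drift, friction, 3D geometry of a physical phantom (the
gelatin block is represented by its 2D mid-section, consistent with the 2D
calibration models), instrument compliance, or batch-to-batch gelatin
variability. Closed-loop tests passing therefore demonstrates the
*method's* consistency and noise robustness, not 3D experimental accuracy.

## Problem sizes used in tests and the acceptance script

The shipped closed-loop studies use a 4-mm mesh on the 100×100-mm domain,
11–13 probe positions spanning 25–75 mm, indentation depths 1/5/10 mm with
10 increments at 10 mm, and coarse libraries (3 nodule depths × 3–4
diameters). These sizes were chosen so a full study builds in minutes on a
single CPU; the recovered values are grid-exact for on-grid truths and the
mesh-convergence and contact-mode checks bound the discretization effects.
The unit-test scenario is smaller still (60×60 mm, 9 positions).

## Known limitations

* Elastic, rate-independent tissue only; no viscoelasticity or damage.
* 2D plane strain: out-of-plane effects and 3D nodule shapes are outside
  the model; forces are per unit thickness.
* Single nodule with a fixed 2:1 stiffness ratio; stiffness itself is not
  estimated.
* The calibration library uses circular nodules; irregular shapes are
  summarized by an equivalent circle, which is exactly the approximation
  the sensitivity studies quantify.
* Prescribed-displacement contact slightly stiffens the response on coarse
  meshes relative to penalty contact (≤3% at 2-mm mesh); both modes are
  available and converge under refinement.
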