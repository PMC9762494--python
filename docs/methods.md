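# Methods

This note documents the models, numerical choices and limitations behind
`eecm`.  Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Scope and overall design

The package characterizes two-phase voxel volumes (solid tissue wall vs.
pore space) the way a scaffold designer would characterize an endoneurium
sample: segmentation → morphometrics → permeability → directional
stiffness.  Two deliberate desk-scale substitutions are made relative to a
full commercial tool chain:

1. **Creeping (Stokes) flow instead of full Navier–Stokes.**  The
   permeability of a matrix with ~10 μm pores is only meaningful in the
   Darcy regime (Re < 1); at the flow rates of interest Re ≈ 10⁻³–10⁻⁶, so
   the inertial terms are entirely negligible and a linear Stokes solve is
   the appropriate model.  The Reynolds number of every image-based result
   is attached, and the validity flag is tied to Re < 1.
2. **Linear voxel homogenization instead of nonlinear tetrahedral μ-FE.**
   Directional effective moduli are evaluated in the linear (post-toe) phase
   of the J-shaped tensile response, where the tangent behavior is linear by
   definition.  The material nonlinearity is carried separately by analytic
   incompressible hyperelastic fits to the uniaxial curve.

## Synthetic data generator

The generator exists so that every downstream stage has inputs with known
ground truth.  All generators are pure functions of their spec (including
the seed); voxel membership is by voxel center, which matches the analytic
counting oracles used in tests.

**Flow fixtures.**  A straight circular channel (Hagen–Poiseuille,
k = πr⁴/(8A)) and a planar slit (plane Poiseuille, k = h³/(12H)) provide
closed-form permeabilities.

**Fiber phantom.**  The endoneurium-like phantom is a bundle of
quasi-parallel tubes (the pore phase) in a solid matrix: Poisson-disc-like
rejection-sampled centers in the transverse plane, sinusoidal centerline
waviness (amplitude = waviness × length, default 0.03), Gaussian radius
spread, and a sinusoidal radius modulation along the axis (default
amplitude 0.45, wavelength 12 μm) that imitates the varicose constrictions
of real axonal channels.  A global radius scale is tuned by bisection
(≤ 30 iterations) until the achieved porosity is within 0.005 of the
target; the report flags failure beyond 0.02.  Defaults (64³ voxels at
1 μm, target porosity 0.355, tube radius 4.6 ± 1.0 μm) were chosen once so
that the *measured* characteristics of the phantom match the physiological
endoneurium values: porosity 35.5%, watershed/ESD pore size ≈ 12 μm
(physiological 11.8 ± 2.8), solid thickness ≈ 12 μm (11.4 ± 3.1), near-unit
longitudinal pore tortuosity.  The domain (64 μm ≈ 5 pore diameters across)
is a scaled-down RVE chosen to keep the test suite fast; the RVE-size
check in `segmentation.assess_rve_convergence` quantifies what that costs
in porosity scatter.

What the phantom does *not* emulate: iodine-staining contrast physics, beam
hardening or reconstruction artifacts; transverse pore interconnections are
present only where tubes overlap, so transverse pore percolation is
seed-dependent (real endoneurium pore space is also strongly anisotropic in
this respect).  Passing tests on phantoms therefore validate the *measure­
ment machinery*, not any claim about real nerve anatomy.

**Curves and permeametry records.**  The piecewise J-curve uses a cubic toe
σ = (E·toe/3)(ε/toe)³ whose slope reaches the linear modulus E exactly at
the toe strain, followed by a straight limb of slope E (defaults: toe 13%,
E 38.5 MPa — typical fascicle tensile values).  Falling-head records are
generated by inverting the analysis equations exactly, so the round trip
recovers the input permeability to < 10⁻³ relative.

## Segmentation

Thresholding polarity is fixed: grayscale strictly greater than the
threshold TV → solid.  The histogram-valley TV picker smooths the histogram
with a width-5 moving average before locating the two dominant local maxima
and returns the lowest minimum bin strictly between them; a unimodal
histogram raises an error advising a manual TV.  Because the valley search
runs on the *smoothed* histogram, an empty valley between two delta peaks
returns the lowest zero bin after smearing (e.g. 53 for peaks at 50/200),
not the first bin after the lower peak — the choice is arbitrary for an
empty valley and is fixed by this convention.

The "solid-area rate" used for calibration is the mean per-transverse-slice
2D solid-pixel fraction, the quantity a stained section measures.  A 3D
surface measure would be an alternative reading; 2D was chosen because the
calibration reference is inherently a 2D histological image.  Calibration
scans a candidate TV list exhaustively and returns the full (TV, rate)
table so the monotone rate-vs-TV curve can be inspected.

The mean filter uses clipped (shrinking) neighborhoods at the volume
boundary so no padding value biases the boundary slices.  The RVE criterion
(porosity SD ≤ 0.01 across random sub-cubes and mean within 0.01 of the
largest edge) is this package's own, configurable definition.

## Morphometry

* **Connectivity** is 26-neighbor for phase components and geodesics, with
  Euclidean edge weights (h, h√2, h√3) — less directional bias than
  6-connectivity.  *Flow* connectivity (Stokes solver) is 6-neighbor, since
  only face-sharing voxels conduct volume flux.
* **Tortuosity** along an axis is the mean over all inlet-face voxels of a
  percolating component of the multi-source Dijkstra distance to the
  opposite face, divided by the domain extent; half a voxel is added at
  each path end so an unobstructed phase measures exactly 1.0.  The mean
  (not the single global minimum, which is noise-dominated) is the headline
  statistic; the minimum is also reported.  The proprietary
  "centerline/shortest-route" definitions used by commercial packages are
  not published, so this definition is declared rather than claimed
  identical.
* **SAVR** is the marching-cubes isosurface area of the solid phase divided
  by total volume, with a Gaussian pre-smoothing of σ = 0.7 voxels: on raw
  binaries marching cubes reads a voxelized sphere ~9% high, while with the
  pre-smoothing spheres measure within ~1% and flat faces within ~4%.
  Domain-boundary faces are never generated, so SAVR measures internal
  interface only and is independent of where the ROI was cut.  A voxel-face
  counting estimate is reported alongside as an independent cross-check; it
  is exact for axis-aligned walls and overestimates oblique smooth surfaces
  by up to 1.5× (√3 in the limit of voxel-scale curvature).
* **Object separation** is marker-based watershed on the negated Euclidean
  distance transform; markers are h-maxima of the EDT with h = 2 voxels by
  default, which suppresses spurious splits from voxelization roughness.
  Every phase voxel gets exactly one label (stray unlabeled voxels are
  assigned by connected components).  Per-object volumes are converted to
  equivalent spherical diameters; the pore-phase ESD is the "pore size" and
  the solid-phase ESD the wall-thickness analogue.

## Image-based permeability

Staggered-grid (MAC) finite volumes on the voxel lattice: pressure at pore
cell centers, velocity on faces, solid as a zero-velocity mask — mass is
conserved exactly per cell.  Boundary conditions: uniform normal velocity
on inlet-plane pore faces carrying the prescribed Q; zero static (ghost)
pressure at the outlet with zero-gradient outflow; no-slip on all solid
interfaces and, by default, on the four lateral domain walls.  Walls
tangential to a velocity face lie half a cell away and are imposed by ghost
reflection, which keeps the physical wall at the solid/pore face: a 1D
Poiseuille analysis of the scheme shows the discrete flux converging from
above (+3.1% at 8 cells across the gap, +0.8% at 16).

Dead-end and enclosed pore pockets (6-connected components not linking
inlet to outlet) are masked out: they carry no flow, and a prescribed
inflow into a dead end would be inconsistent.

The saddle-point system [[A, G], [Gᵀ, 0]] is solved by conjugate gradients
on the pressure Schur complement Gᵀ A⁻¹ G (spectrally a mass matrix, so the
outer iteration converges in tens of iterations), with the three SPD
viscous blocks factored once by SuperLU in symmetric-mode minimum-degree
ordering.  Momentum is then satisfied to machine precision and the
divergence residual is the outer CG tolerance (defaults: relative 10⁻¹⁰;
measured ~10⁻¹² in the validation runs).

**Pressure-drop measurement.**  A uniform inlet profile needs a development
length, and the enclosed-cell entrance excess would bias ΔP by ~10–20% on
the 64³ fixtures.  ΔP for Darcy's law is therefore measured between the
pore-area-mean pressures of two interior planes (default the 25% and 75%
axial positions) with the matching flow length; the full inlet-to-outlet
drop is also reported.  For the laterally-unbounded closed forms (plane
Poiseuille) a `free_slip` lateral-wall option reproduces the translational
symmetry the formula assumes; the default remains enclosed no-slip walls.
With these choices the solver matches Hagen–Poiseuille within 1% and plane
Poiseuille within 1% at 64³ (acceptance band 10%), permeability is
independent of Q to ~10⁻¹⁴ relative, and k scales exactly with
voxel-size².

**Falling-head analysis** is pure algebra: K = aH/(A·t)·ln(L1/L2), then
k = Kμ/(ρg) with water defaults (ρ = 1000 kg/m³, μ = 10⁻³ Pa·s,
g = 9.8 m/s²).  The degenerate no-drop record (L1 = L2, t = 0) returns
K = 0.  Aggregation over samples reports the arithmetic mean and the
population (divide-by-n) SD, which is what the bundled reference table
uses.

### Bundled worked-example records

`eecm.datasets` carries the published falling-head and CFD-permeability
records the analysis equations are exercised against.  Three internal
inconsistencies of the printed records were found and are preserved rather
than corrected (see the module docstring): the single-trial table's printed
sample height (1.00×10⁻¹ m) overshoots its own printed conductivities by a
factor of ~10 — `pipeline.audit_falling_head_height` demonstrates
numerically that H = 1.00×10⁻² m is the consistent value; one triplicate
permeability has an exponent typo (7.33×10⁻¹² vs the 7.33×10⁻¹³ its own K
implies); and one triplicate conductivity (8.23×10⁻⁶ m/s) matches neither
its own elapsed time nor its own permeability and is flagged
``discrepant``.  The reported experimental average of 2.19×10⁻¹² m² is not
the arithmetic mean of the nine triplicate permeabilities (≈1.04×10⁻¹¹);
the aggregation that produced it is unknown and is not reproduced.

## Mechanics

**Curve analysis.**  The linear region of a J-curve is found in two stages:
(1) the widest sliding window (≥ 30% of the points) whose linear fit
reaches R² ≥ 0.99; (2) since a wide window tolerates a gently curving tail,
the toe boundary is refined against a reference line fitted to the upper
half of that window — scanning from high strain down, the toe is placed at
the first two consecutive points whose residual exceeds
max(3 × reference RMS, 0.5% of peak stress), and the modulus is refit above
that boundary.  A window-start rule alone systematically underestimates the
toe of smooth J-curves by several strain percent at R² = 0.99, which is why
the refinement stage exists.  On the noiseless default J-curve the
estimator returns the modulus exactly and toe strain 12.1% (construction
13%); at 1% noise the modulus is recovered within 3%.

**Hyperelastic fitting** uses nominal (first Piola) stress — machine force
over undeformed area.  Neo-Hookean, Mooney–Rivlin and Yeoh are linear in
their coefficients and fitted by exact linear least squares; first-order
Ogden (Abaqus convention, σ = 2μ₁/α₁(λ^{α₁−1} − λ^{−α₁/2−1})) by bounded
nonlinear least squares seeded from the initial slope.  Marlow is excluded
(non-parametric) and Ogden restricted to first order for least-squares
stability.  A fit is "stable" if its tangent modulus stays positive over
the fitted stretch range.  Model selection ranks stable fits by MSE with a
5% relative tie tolerance favoring fewer coefficients — a nested richer
model never fits worse, so the tie rule is what lets the generating special
case win (verified on neo-Hookean data against its Mooney-Rivlin/Yeoh
supersets).

**Voxel homogenization.**  Every solid voxel is a trilinear 8-node
hexahedron (2×2×2 Gauss, exact); pore voxels are void.  Rigid-plate loading
along an axis: uniform axial displacement on the loaded face's solid nodes,
axial fixity on the opposite face, lateral components free everywhere,
plus minimal per-component point constraints to remove lateral rigid-body
modes.  Only vertex-connected solid components spanning both plates carry
elements — fragments touching one or neither plate bear no load but would
make the stiffness singular.  E = F·l/(u·A) uses the full cross-section A
(voids included), so 0 ≤ E ≤ (solid fraction)·E_solid always (Reuss/Voigt
bounds for this void-series/parallel setting).  The default Poisson ratio
is 0.49 (near-incompressible soft collagenous solid), configurable.

The constrained SPD system is solved by SuperLU below 40k dofs, otherwise
by conjugate gradients with a 3×3 nodal block-Jacobi preconditioner and a
uniform-axial-strain initial guess (relative tolerance 10⁻⁷; 10⁻⁶ suffices
for the qualitative anisotropy runs and is used there).  Near-incompres­
sibility makes the system ill-conditioned — ν = 0.49 costs roughly 5× the
iterations of ν = 0.3 — and trilinear elements lock mildly in bending-
dominated geometries at high ν; both effects are irrelevant to the
homogeneous-deformation oracles (cube, laminate) and acceptable for the
qualitative longitudinal-vs-transverse ordering on tube phantoms.

Validation: a fully solid cube returns the solid modulus to ~10⁻¹²
relative; a half-void laminate loaded in-plane returns the Voigt value
f·E_solid (exact for that geometry) and 0 through-thickness; the default
48³ tube phantom gives E_z ≈ 51 MPa vs E_x ≈ 36, E_y ≈ 37 MPa at
E_solid = 100 MPa — longitudinally stiffer, as an aligned tubular matrix
must be.  `calibrate_solid_modulus` exploits linearity: one unit-modulus
solve, then solid_modulus = target/E_unit, optionally verified by a
confirming solve to 1%.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at: 64³ for flow fixtures
and the end-to-end phantom (flow solve ~20–40 s each on one core), 48³ for
the anisotropy homogenization (~2 min per axis at ν = 0.49), 24³–32³ for
the remaining voxel-FEM checks, 50–100 points for curve fits with 20-seed
noise ensembles.  These sizes were chosen as the smallest at which the
analytic oracles discriminate clearly (e.g. channel discretization error
~1% at r = 16 voxels, voxelization porosity error < 3%).

## Known limitations

* Tortuosity and watershed definitions are declared conventions; different
  packages (and the commercial modules they emulate) will differ by a few
  percent on the same volume.
* The Stokes solver is single-phase, Newtonian, steady and enclosed; no
  Forchheimer correction, transient or periodic-lateral option beyond the
  free-slip flag.
* Trilinear displacement elements at ν = 0.49 overestimate stiffness in
  bending-dominated microstructures (no incompatible modes / B-bar); the
  homogenization is meant for ranking and calibration, not for certifying
  absolute moduli of complex geometries.
* The fiber phantom reproduces summary statistics of endoneurium
  microstructure, not its full geometry statistics; conclusions about real
  tissue require real volumes.
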