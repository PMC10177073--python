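# Methods

## Model and assumptions

The package solves the optical diffusion approximation for the fluence
rate φ (mW/cm²) in heterogeneous tissue at 630 nm. In the transient weak
form the operators are assembled exactly as: plain mass (time
derivative), diffusion stiffness weighted by α_n = c_n·D (cm²/s),
absorption mass weighted by c_n·μ_a, and an outer-boundary Robin mass
weighted by c_n. At steady state — the planning default, since the
photon field equilibrates on the 1/(c_n μ_a) ≈ 0.1–1 ns timescale — the
c_n factors cancel for a uniform refractive index, which a test verifies.
Assumptions inherited from the planning problem:

* optical properties are constant during illumination (no
  photobleaching, no thermal coupling);
* diffusers emit uniformly along their length, modeled as a Dirichlet
  surface value P_laser on the fiber wall;
* the Robin condition is φ + D ∂φ/∂n = 0 as printed in the planning
  literature, with no internal-reflection index-mismatch factor — with a
  ≥10 cm domain and μ_eff ≈ 1.9 1/cm the boundary term is irrelevant to
  every reported quantity;
* fibers illuminate **sequentially** (one at a time), so the irradiance
  criterion applies per fiber and fluence accumulates across
  illuminations. A `simultaneous` flag provides the combined-field
  reading for comparison.

Units are fixed internally: lengths cm, irradiance mW/cm², fluence
J/cm² (mW·s/1000, converted exactly once at accumulation), power mW,
intensity mW/cm, time s.

## Source model

A clinical CDF is specified by intensity I (mW/cm) and diffuser length L;
its total power is I·L. The Dirichlet value is

    P_laser = I·L / (π d L + 2π (d/2)²),

total power over the total (lateral + end-cap) surface area, conserving
the prescribed output power over the nominal source surface. The same
area enters the treatment-time identity t = F·A/P, so an unquantized plan
reproduces its initial treatment time exactly. The diffuser diameter is
not part of the clinical prescription; the default is 0.98 mm (a typical
clinical diffuser) and it is recorded in every report.

In the phantom mesh the fiber occupies a full-height cylindrical channel
(physically, the fiber/catheter shaft fills the insertion track); the
Dirichlet band is the lateral diffuser surface and the shaft wall above
and below is a natural (zero-flux) boundary. This choice keeps the
revolved structured grid free of degenerate on-axis elements. End caps
therefore do not exist as mesh surfaces; their ~2.4% share of the nominal
area is retained in the P_laser conversion for power conservation.

During a single-fiber solve the other diffuser surfaces are held at
φ = 0 (perfectly absorbing dark fibers). This convention makes
single-fiber solutions superpose exactly to the all-on solution — the
property the dose accumulation and the optimizer's no-re-solve scaling
rely on — and is tested at 1e-10 relative.

## Meshes

Two deterministic structured generators (identical inputs ⇒ identical
meshes, no randomness):

* **Phantom**: a revolved annular grid around the fiber axis. Radial
  spacing starts at d/10 on the fiber wall (sub-radius resolution is
  required because the near field is K0-like), grows geometrically
  (ratio 1.3) to a 0.16 cm cap through the detector shell and 0.32 cm
  beyond — the far cap stays below the 1/μ_eff ≈ 0.53 cm attenuation
  length so the exponential decay remains resolved. Azimuthal count is a
  multiple of 8 (nodes land exactly on the cube diagonals, so the outer
  ring maps exactly onto the square cross-section); the axial grid has
  nodes exactly at the diffuser band edges. `target_h` rescales the whole
  grading; the default (0.49) yields ≈54k nodes / 307k tetrahedra and
  detector values within ~2–5% of the h→0 limit (established with the
  convergence utility and an independent axisymmetric finite-difference
  solve).
* **Airway scenes**: a graded Cartesian tensor grid with fine windows
  around each fiber, split 6-tets-per-hex (Freudenthal; conforming on
  structured grids). The bronchus and the diffuser segments are carved as
  staircase cavities by centroid distance; regions (ellipsoidal tumor,
  cylindrical vessels, normal tissue) are tagged by element centroid.
  The carved fiber surface area therefore differs from the nominal
  cylinder at coarse resolution — acceptable for planning logic, whose
  safety quantities live centimeters from the source, and irrelevant to
  the linearity/safety properties the tests assert.

Scene invariants enforced on every build and on every file read: positive
element volumes, and the tagged boundary facet set equals the topological
boundary exactly (watertight per tag).

## Numerical choices

* P1 elements; sparse direct factorization (SuperLU) up to 200k free
  nodes, Jacobi-preconditioned CG above; relative residual ≤ 1e-10,
  recorded in each field's metadata.
* Dirichlet values are imposed by row elimination and attained exactly.
* The discrete flux identity (source reactions = absorbed + Robin
  outflow) holds to solver precision and is tested at 1e-8.
* P1 on graded anisotropic meshes does not satisfy a strict discrete
  maximum principle: the solution undershoots zero by up to ~1e-3 of the
  source value on coarse grids (~1e-5 at the production scale), in the
  far field where φ has decayed to ~1e-4 of the source. The undershoot
  shrinks under refinement (tested) and is left in place — clamping would
  mask discretization error.
* Power quantization floors onto the 20 mW grid with a 1e-9 guard
  against floating-point near-misses; a fiber quantized to zero power is
  off and contributes no fluence.
* Domination ties (exact equality between fibers) leave a node in no
  sub-map, matching the strict-inequality definition; a config flag
  assigns ties to the lowest fiber id instead. In the fluence-scaling
  loop a tied peak node scales all contributors proportionally.
* The TUD +∞ sentinel (a fiber dominating no vessel node) is resolved by
  the 400 mW/cm intensity cap before any arithmetic uses it.
* TUD iteration: factors are applied even when all fibers are already
  safe (factors > 1 raise power — the purpose of the method), iterating
  to a fixed point with max_iter = 10; afterwards any still-unsafe fiber
  is rescaled directly by limit / (its own vessel maximum), which
  terminates unconditionally. Emitted plans are re-audited by direct
  recomputation; an unsafe plan raises instead of being returned.

## Dose-volume bookkeeping

Volume fractions classify each tetrahedron by the mean of its four nodal
values, weighted by element volume — deterministic and mesh-consistent;
sub-element interpolation is a refinement the metric definitions do not
call for. Threshold comparisons are inclusive (≥). The effective
rate-based dose counts an element when it meets both the rate criterion
(per-fiber maximum ≥ 8.6 mW/cm²) and the fluence criterion (rate-gated
fluence ≥ 45 J/cm²); with `effective_mode="total"` the total fluence is
used at rate-qualified points instead (the alternative reading of the
metric). Safety maxima over critical structures use nodal maxima — the
conservative direction.

## Agreement statistics

Lin's concordance correlation coefficient with population (divide-by-n)
moments; the estimator is convention-consistent since numerator and
denominator share the moment definition. The 95% CI uses the asymptotic
normal approximation of the Fisher z-transform with Lin's 1989 variance,
back-transformed and clamped to [−1, 1]; the method is recorded in the
result. With n = 5 the CI method materially affects digits, so only point
estimates are treated as exact in tests. The phantom bench columns
reproduce the published agreement values (0.999 measured-vs-Comsol,
0.994 measured-vs-Dosie) to three decimals.

## The phantom near-field discrepancy

At the 5 mm detector the package computes ≈ 56 mW/cm² against the
published solver values 47.0 (Comsol) and 50.5 (Dosie) and the bench mean
46.7 ± 3.4. Three mutually independent solutions of the same stated model
— this package's FEM, a fine axisymmetric finite-difference solve
(55.3), and a calibrated finite-line-source quadrature (53.7) — agree
with each other, so the gap is not a solver defect. Two effects plausibly
explain it: (i) the two published solvers disagree with each other by 7%
at this point, consistent with limited mesh resolution around a 1 mm
fiber in a 10 cm domain, which biases the near field low; and (ii) 5 mm
is only ≈ 2.6 transport mean free paths from the source, where the
diffusion approximation itself overestimates the fluence rate relative
to transport. From 10 mm outward the computed profile matches the
published values within ~3–13% and the CCC against the measurements is
0.975–0.977, above the published lower confidence bound (0.953). The
corresponding acceptance check at the 5 mm point is left failing rather
than tuned away.

## What the synthetic scenes do and do not show

The airway fixtures emulate the geometric structure of the clinical
problem — an ellipsoidal tumor abutting a bronchus, vessel-like critical
structures, oblique fiber insertions with the 30–40°, ≤ 4 cm, ≥ 6 mm
placement rules — with published soft-tissue and blood optical
properties. They do not reproduce patient anatomy, image segmentation,
heterogeneous tissue composition, or clinical fiber counts; passing
tests demonstrate the correctness and safety of the planning machinery,
not patient-level dosimetry accuracy. Problem sizes used in the test
suite (3k–80k nodes) and the acceptance script (~54k nodes / 307k
tetrahedra) were chosen by the convergence study as the smallest grids
whose quantities of interest are mesh-converged at the few-percent
level.

## Known limitations

* Diffusion approximation only; no Monte Carlo transport. Near-source
  (< 3 transport mean free paths) values are upper estimates.
* No photochemistry: photosensitizer distribution, oxygen and
  photobleaching are outside the dose model, which is purely optical.
* Fiber positions are inputs; the package checks placement constraints
  but does not search over positions.
* Airway fiber cavities are staircase approximations; phantom-grade
  near-field accuracy is only claimed for the revolved phantom mesh.
* The CI method for the concordance coefficient is asymptotic and
  n = 5 sits at the edge of its validity; intervals are reported with
  their method label and not treated as exact.
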