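# Methods

This note documents the models, numerical choices and verification design
behind `plaquemech`, at the level of detail a user needs to judge what the
package's passing tests do and do not demonstrate.

## Problem setting

A diseased vessel segment is represented as a quadratic simplex mesh
(10-node tetrahedra in 3D; 6-node triangles in the 2D plane-strain desk
mode) with one tissue label per element, from the set {artery, mixed,
fibrous, lipid, calcium}. Two geometries of the same segment are assumed
available, acquired at known intraluminal pressures; the inverse problem is
to find the material parameters of every tissue class such that simulating
the base geometry under the pressure differential reproduces the target
geometry. The base configuration is treated as stress-free — the standard
simplification when the zero-pressure geometry is unknown; recovering a
zero-pressure configuration is out of scope here and would slot in upstream
of this package.

## Constitutive models

**Linear elastic.** σ = Eε with a fixed Poisson ratio ν = 0.49. The tissue
is physically near-incompressible; 0.49 keeps a displacement-only
formulation well conditioned. Only E per tissue is recovered.

**Yeoh hyperelastic.** W = C10(Ī₁−3) + C20(Ī₁−3)² + C30(Ī₁−3)³ in the first
deviatoric invariant Ī₁ = J^(−2/3) tr(FᵀF) — the standard stretch-based
Yeoh invariant. Near-incompressibility is enforced by U_vol = κ/2 (J−1)²
with κ = 1000 μ0 = 2000 C10 per material, so each tissue's volumetric
stiffness scales with its shear stiffness. The initial shear modulus is
μ0 = 2 C10; the small-strain Young's modulus 6 C10 (verified against the
linear model within 2% at ≤1% strain).

C30 is held at its assigned value during recovery: simulated uniaxial
response is sensitive to the cubic term only above ~20% strain, and the
verification loading peaks below 8% (the forward model reports its peak
stretch as a diagnostic and warns past 20%). Calcium parameters are
likewise excluded whenever the calcium volume fraction is below 1% — in the
default phenotype it is ~0.3% — giving 4 free parameters in the linear mode
and 8 in the Yeoh mode (C10, C20 for artery/mixed/fibrous/lipid). Two
additional calcified phenotypes (calcium > 1%) exercise the 9-parameter
mode that adds the calcium C10.

Ground-truth values and search ranges ship as a package data file
(`data/material_table.yaml`), user-overridable through the run
configuration. Ranges span roughly one order of magnitude per parameter;
the calcium C10 range for the 9-parameter mode is one order of magnitude
around its assigned 1270 kPa (the source protocol does not state one).

## Forward solver

Quadratic simplices are used throughout to mitigate volumetric locking at
near-incompressibility. Assembly is vectorized over elements (degree-4
triangle / degree-5 tetrahedron quadrature on the curved isoparametric
geometry).

* **Linear mode:** infinitesimal strain, pressure applied as a consistent
  nodal load on the *reference* inner surface, single sparse solve. Per-
  tissue unit-modulus stiffness matrices are cached, so re-solves during
  optimization reduce to a modulus-weighted matrix sum plus one
  factorization.
* **Yeoh mode:** total-Lagrangian finite strain, follower pressure on the
  deformed inner surface, Newton-Raphson over ≥4 load steps with adaptive
  substep halving. The exact (unsymmetric) follower-load stiffness is
  assembled in 2D but only added once the residual is within 5% of the
  load norm — far from the solution it destabilizes the iteration, near it
  it restores the quadratic rate; in 3D it is omitted and load stepping
  compensates. Newton tolerance is 1e-8 on the force residual relative to
  the load scale, with a stagnation acceptance at the roundoff floor of the
  penalized system (relevant below ~1e-6 relative). Within an optimization
  the solver warm-starts from the previous converged state, which makes the
  small parameter moves of gradient evaluations nearly free.

Boundary conditions: both end caps are fixed axially (3D); the in-plane
rigid modes are removed by zeroing the circumferential displacement at
three outer-surface nodes ~120° apart. These constraints are compatible
with an axisymmetric response (they are exactly satisfied by the
thick-walled-cylinder solution used as the linear benchmark) and rotate
with the geometry, preserving objectivity.

Pressures are entered in mmHg and converted internally
(1 mmHg = 0.133322 kPa); lengths are mm and moduli kPa.

## Objective

For node sets 𝒩 (one per tissue class present, plus inner and outer
surfaces), each pair with common nodes is an interface, and its error is
the mean Euclidean distance from target interface nodes to the nearest node
of the corresponding deformed interface. The error is directional
(target → deformed) exactly as defined, not symmetrized; nearest-neighbor
queries use a k-d tree whose result equals exhaustive search. Interfaces
with fewer than three common nodes are dropped with a warning (a one-node
"interface" makes the mean degenerate). δ_MO is the vector of interface
errors, δ_SO their sum.

Two macro-morphological baselines support comparison studies: `surface`
applies the same nodal distance to the full inner and outer surface sets
only, and `diameter` compares the minimum/maximum luminal Feret diameters
on evenly spaced cross sections (2D: the section itself; defaults: 10
slices, contour = inner nodes within half the axial node spacing of the
slice plane, 180 caliper directions). The diameter construction is an
artifact choice — the original baseline's exact slice count and diameter
definition are not specified anywhere authoritative.

## Two-stage optimization

Free parameters are log10-mapped to [0,1] over their search ranges (ranges
span 1–2 decades, so log scaling equalizes relative steps).

**Stage 1 — NSGA-II** on δ_MO: Latin-hypercube initial population
(scipy qmc; exactly one sample per 1/n stratum per dimension), binary
tournament on (rank, crowding), simulated binary crossover (p=0.9, η=15),
polynomial mutation (p=1/n, η=20), elitist environmental selection. Budgets
follow the verification protocol: population 24 over 7 generations (linear)
or 24 (Yeoh). Failed forward solves receive infinite fitness. With ~8
objectives the non-domination pressure is weak and the stage acts mostly as
a structured global sampler — which is why incumbent selection uses the
minimum δ_SO across *all* generations, not the final front.

**Stage 2 — SQP refinement.** The local stage is a bound-projected damped
Gauss-Newton (Levenberg-Marquardt) sequential quadratic method on the
interface-error *vector*: a forward finite-difference Jacobian (n
simulations per model build; n+1 per accepted point) defines the quadratic
model, steps are accepted only on strict decrease of δ_SO, and the damping
diagonal is floored at 1e-3 of its maximum so that directions whose
finite-difference column is curvature noise stay bounded. Exploiting the
least-squares structure matters: δ_SO is norm-like (positively homogeneous)
near its zero, which defeats quasi-Newton methods on the scalar — a
scalar-SQP reference implementation needed ~7× the simulation budget to
reach the same accuracy. Three further ingredients, all within the same
simulation budget of `sqp_max_evals × (n+1)`:

* a *shrinking difference step* (3e-4 → 1e-5 → 1e-6 in scaled space),
  because the useful secant step of a cone-shaped objective tracks the
  distance to the minimizer;
* *geodesic acceleration* (one extra simulation per step), a second-order
  correction that speeds traversal of the curved valleys produced by
  C10/C20 compensation;
* *restarts* from up to two runner-up individuals of the global stage,
  selected by per-dimension distance weighted with the spread of the best
  trace points — the directions along which good individuals scatter are
  the poorly determined ones, and that is where basin diversity pays off.

Stop rules: successive-objective decrease below `sqp_residual` (default
1e-9) at the final difference step, or budget exhaustion. The returned
vector is the best point actually evaluated, so δ_SO is monotone over the
stage, and every evaluated point lies within bounds. Every evaluation of
both stages is recorded in an append-only trace from which the incumbent
and the final answer are reconstructible.

## Synthetic verification vessel

The generator builds a straight thick-walled annulus (inner radius 1.5 mm,
wall 1.0 mm — a plausible diseased coronary) on a structured polar grid,
with midside nodes on the polar mid-surfaces so the luminal boundary is a
curved isoparametric circle (the annulus area is exact to ~1e-6 at the
study resolution). Intramural inclusions are angular wedges over radial
bands, overriding the artery background by centroid membership; labeling by
nearest annotated point (with lowest-index tie-breaking) is also available
for point-cloud-driven workflows. The default layout reproduces the
reference lesion's tissue prevalences (artery ≈ 64.6%, fibrous ≈ 19.3%,
lipid ≈ 13.0%, mixed ≈ 2.9%, calcium ≈ 0.3%), with lipid and mixed strictly
intramural — they touch no wall surface, which is what makes the
surface/diameter baselines measurably worse for them.

What the synthetic vessel does *not* emulate: irregular lumen and wall
contours, axially varying morphology, meshing error between the two imaged
states (both geometries share one topology here), pre-stress in the base
configuration, and tissue-internal heterogeneity. Passing the verification
therefore demonstrates the method's internal consistency (an inverse-crime
setting with a known exact optimum) and its noise robustness — not accuracy
on clinical reconstructions.

Verification studies run at desk scale: 2D plane strain, 24×4 cells (432
nodes, 576 quadratic triangles), chosen so a full two-stage linear recovery
takes seconds and a Yeoh recovery about a minute on one CPU. The studies
mirror the reference protocol: ΔP = 60 mmHg, 60 mmHg being the high end of
physiological pulse pressure; noise-free linear recovery (4 moduli);
8-parameter Yeoh recovery; displacement-noise studies at n = 5% and 20% of
the peak displacement (the noise multiplies each displacement *component*
by 1 + z, z ~ N(0, n·max|u|) — the literal elementwise reading; a per-node
vector scaling would correlate the components of a node and is rejected);
pressure perturbation of the target generation by ±5%/±10%; and paired
objective-mode comparisons on identical seeds. The default seed list is
1..8, mirroring the 8-run protocol; reduced CI budgets use its first 3–4
seeds.

## Known limitations

* The 8-parameter Yeoh recovery at desk scale has a residual failure mode:
  the lipid C20 (weakest sensitivity, ~30× below the strongest parameter at
  this strain level) sits in a long shallow valley with secondary basins.
  Across 17 tested seeds, 15 runs recovered every parameter within 10%
  (most within 5%); two landed at 15–27% on lipid C20. More budget does not
  fix this (the basins persist at 4× budget) — richer geometry data would.
* The 2D plane-strain mode is a verification vehicle; the mechanics of real
  lesions (out-of-plane stress, axial taper) need the 3D mode, which is
  implemented but substantially slower per solve.
* Surface meshes are compared node-to-nearest-node, not point-to-triangle;
  at very coarse resolution the discrete contour introduces
  polygonal-chord bias in the diameter baseline.
* NSGA-II with ~8 objectives exerts little selection pressure; its value
  here is structured global sampling. A scalarized or decomposition-based
  global stage might be stronger, but the two-stage structure is part of
  the method being verified.
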