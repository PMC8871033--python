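# Methods

This note records the modeling choices, parameter defaults and numerical
conventions behind `septalflow`, and what the synthetic benchmarks do and
do not establish.

## Flow and scalar model

The solver is a D3Q19 lattice Boltzmann method with single-relaxation-time
(BGK) collision and two populations: `f_i` carrying mass and momentum and
`g_i` carrying the dimensionless blood-oxygen content `C_b`.  Everything
runs in lattice units (`δx = δt = 1`, `cs² = 1/3`, reference density
`ρ0 = 1`); physical scales enter only through post-processing (the entropy
prefactor `μ/T`) and through however the user maps lattice velocities to
physical ones.  There is no external force term: flow is driven entirely
by the boundary conditions, which matches the quasi-steady framing of a
heart driven by port pressures rather than a body force.

Assumptions inherited from this model class: weakly compressible low-Mach
flow (all runs keep `|u| < 0.1` lattice units, enforced by an explicit
guard that raises rather than clips), Newtonian rheology, rigid walls,
and a passive scalar (oxygen content does not feed back on the flow).

### Transport coefficients

`μ = ρ cs²(1/ω_f − 1/2)` and `α = cs²(1/ω_g − 1/2)`.  These are not taken
on faith: the test suite fits the Taylor–Green kinetic-energy decay
(`E ∝ exp(−4νk²t)`) and a sinusoidal scalar mode decay
(`∝ exp(−αk²t)`) at 64³ and requires the fitted coefficients within 1% of
the formulas.  Fits discard the first ~2 sample windows (initial acoustic
transient) and regress `log E` on time.

### Boundary conditions

* **Walls** live mid-link (half-way bounce-back): the solid voxel layer is
  the wall, and the no-slip plane sits half a spacing outside the last
  fluid node, second-order accurately.  A 3-resolution channel refinement
  test checks that the extrapolated wall velocity decays at order ≳ 1.5.
* **Scalar walls** are adiabatic (zero oxygen flux) via specular
  reflection: the post-collision `g_i` travels one step along the
  tangential velocity `c* = (c_i + c_i′)/2` and arrives in the mirrored
  direction `i′`.  The mirror is only well defined where the local wall
  has an unambiguous axis normal (exactly one of the six axis neighbours
  solid).  At edges, corners and other ambiguous voxel configurations the
  link falls back to plain bounce-back — which is also the exact rule for
  purely normal links — and a repair pass demotes any specular assignment
  that would leave some incoming slot unfilled or doubly filled.  After
  construction every population slot has exactly one source, which is the
  property that makes total scalar mass conserved to round-off in closed
  domains (asserted at 1e-10 over 1000 steps; measured ~1e-13).
* **Inlets** either impose a velocity (populations replaced by
  `f^eq(ρ_interior, u_inlet)`) or a pressure (fixed density with
  zero-gradient velocity).  Oxygen at class-`low`/`high` inlets is pinned
  through `g^eq(ρ, ∓1, u)`.
* **Outlets** are free-flow: zero-gradient velocity and non-equilibrium
  part, with the density anchored at `ρ0`.  A fully zero-gradient
  population copy was tried first and rejected: with equilibrium inlets it
  leaves the system's pressure level floating, and mass grows without
  bound (a measured +23% density drift over 1800 steps in a duct).  The
  anchor makes the outlets the pressure reference; the residual
  inlet/outlet imbalance remains visible in the run diagnostics
  (`flux_imbalance`), typically below 1% of throughput for smooth inlet
  profiles and a few percent for uniform ones.

Step order is fixed — collide, then one gather per population that
realizes streaming plus all wall reflections, then the port update — so
conservation diagnostics are bit-reproducible.  The inner collision and
gather loops are numba-compiled; geometry preprocessing turns all
boundary logic into index tables, so the hot loop contains no branching.

### Convergence and diagnostics

`run_to_steady` iterates in windows of 100 steps and stops when the
relative L2 change over a window of **both** the velocity and the oxygen
field drops below `conv_tol`.  (Velocity alone converges much earlier
than the scalar in shunt problems; using only `u` was observed to stop a
defect-open run thousands of steps before the orifice mixing had
developed.)  Every result carries mass/scalar-mass befores-and-afters,
per-port fluxes, the maximum speed and the `C_b` overshoot beyond [−1,1]
(reported, bounded ~1% in practice, not clamped).

## Segmentation

The growth equation is integrated per 2-D slice with a 5-point Laplacian,
Neumann image edges and explicit step `dt = 0.2` (stability bound 1/4 for
a unit-spacing 2-D Laplacian with growth factor ≤ 1).  `C1 = 1` by
default, so the growth factor equals the local gray level; `C2 = 0.7`.
Voxels accelerated past `C2` are frozen at 1, making the extracted set
monotone non-shrinking — the property the suite asserts.

Two choices here were genuinely open and were settled empirically on the
disk oracle (a sharp bright disk whose true boundary is known):

* **Stopping.**  Evolution stops when the largest pre-threshold update
  `max|dR|` over not-yet-extracted pixels stays below `tol = 0.10` for 40
  consecutive iterations.  The update at a front scales with the local
  growth factor (≈ intensity), so this brake halts the front where the
  blurred intensity ramp has fallen to roughly half the lumen level —
  i.e. at the half-intensity surface, which is the boundary sought.  The
  persistence window bridges the bursty quiet intervals that threshold
  acceleration produces.  With `tol = 0.10` the disk contour lands within
  ±1 px of the analytic circle and the phantom recovery reaches Jaccard
  ≈ 0.93; smaller tolerances let the front creep ~1–2 voxels into the
  blurred wall before stopping (measured +1.3 px bias at `tol = 0.05`).
* **Seeding.**  Automatic seeds are the *interior cores* (distance
  transform ≥ 2 px) of each bright Otsu component per slice, not single
  centre points: an isolated pinned pixel feeds the diffusion too slowly
  to ever launch a front (verified: a point seed stalls indefinitely),
  and core seeding also equalizes evolution times between large chambers
  and thin tubes, so slow leakage into tissue stays uniform.  Point seeds
  passed explicitly are dilated to radius-2 disks for the same reason.

Contours are marching-squares 0.5-isolines with the `fully_connected =
'high'` saddle rule (ambiguous cells connect through the object side);
the field is padded below-level first so objects touching the image
border still close.  Slice fusion: per-slice rasterization (even-odd for
nested contours), signed distance transform, linear inter-slice
interpolation onto unit-spaced planes, threshold at zero, 3³ median
filter.

## The phantom and the study conditions

The phantom abstracts a septal-defect heart to the topology that matters:
two ellipsoidal chambers (semi-axes 12×15×15 voxels in a 48³ box),
a planar septum, a cylindrical orifice of radius 3 through it, and four
port tubes.  Defaults worth justifying:

* **Septum thickness 4 voxels** — at least 4× the default rendering blur
  (σ = 1 voxel), so the wall survives partial-volume smearing; a 3-voxel
  septum under the same blur is marginally resolvable and leaks in
  segmentation.
* **Driving**: pressure inlets at densities 1.03 (pulmonary-vein side)
  and 1.01 (vena-cava side), outlets at 1.0.  Pressure driving, not
  velocity driving, is what reproduces the physiology of a shunt: the
  heart maintains chamber pressures, and the defect adds a parallel leak
  path, so the open geometry carries *more* total flow plus a dissipative
  jet.  (Velocity inlets fix the throughput, which forces the filled
  geometry to push the same flow through fewer paths at higher speed —
  inverting the dissipation comparison for reasons that have nothing to
  do with the defect.)  The resulting speeds are ~0.016 lattice units at
  the jet: low-Mach, viscous-jet regime.
* **Initial oxygen** is stratified by compartment (+1 left of the septum,
  −1 right) — the state the circulation maintains — so a run resolves
  the flow and the defect-driven mixing rather than a full washout whose
  timescale (several chamber turnovers) would dominate the run length.
* **Comparison horizon**: both runs use the same fixed step budget
  (6000 steps at 48³ in the benchmarks).  The open configuration has a
  slow scalar relaxation mode (gradual enrichment of the receiving
  chamber), so its outlet oxygen level is still drifting slowly at that
  horizon; all compared quantities are directionally stable from ~2000
  steps on.
* `ω_f = 1.0` (ν = 1/6) and `ω_g = 1.6` (α ≈ 0.042, port-scale Péclet
  ≈ 20): laminar flow, advection-dominated but resolved oxygen transport.

### What the phantom does and does not establish

The renderer emulates the gross features of a CT stack — two-level
contrast, Gaussian partial-volume blur, additive Gaussian noise, seeded
and reproducible.  It does not emulate beam hardening, streak artefacts,
anisotropic slice spacing, cardiac motion, or anatomically realistic
four-chamber geometry with valves.  Passing tests therefore show that the
pipeline's stages are individually correct against analytic oracles and
mutually consistent end to end; they do not show that the segmentation
defaults or the qualitative pre/post contrasts transfer to real patient
imagery, whose geometry and noise are far richer.  Patient-specific
magnitudes (absolute entropy levels, oxygen minima in named vessels) are
out of reach without a real geometry and are not claimed.

## Entropy analysis

Gradients: second-order central differences on interior fluid nodes,
first-order one-sided next to walls, zero on isolated nodes.  On an exact
parabola the stencil is exact; the convergence-order test therefore uses
a sinusoidal shear profile (curvature beyond quadratic) and checks
second-order decay of the worst-case interior error.  `Ṡ_u ≥ 0` holds by
construction (sum of squares); linearity in `μ` and `1/T` is asserted by
recomputation.  In lattice units `μ/T` is an overall scale, so pre/post
comparisons are unaffected by the choice of `T` (default 310 K, body
temperature, for physical-unit output).

PDFs: 60 log-spaced bins over the positive data range with a dedicated
zero bin (uniform regions produce exact zeros); speed PDFs use linear
bins from zero.  Comparisons bin both runs on a common edge set; tail
masses are reported one and two decades below the open run's maximum.

## Degenerate inputs and tie-breaks

* Constant indicator fields: no contours (level never crossed), not an
  error; all-empty slices reject integration.
* An orifice radius below 0.5 voxel produces no hole (degenerate open
  defect: two components, and the phantom validator expects that).
* Marching-squares saddles: resolved through the object side, documented
  above; the chosen rule only matters at exactly-level plateaus, which
  the indicator field's freeze-at-1 dynamics avoid.
* `ω ∉ (0, 2)`, negative `μ`/`α`/`T`, supersonic or guard-violating
  velocities, empty seeds, non-normalized images, leaky domains and
  off-hull ports all raise typed errors listing the offending quantity
  (leak errors list the offending voxels).

## Problem sizes

Benchmarks run at the sizes a laptop-class CPU handles in minutes:
transport-coefficient fits at 64³ (and 32³ in the examples), the
channel oracle at 40×4×19, conservation at 10³ over 10³ steps, and the
pre/post pair at the phantom's native 48³ for 6000 steps per geometry.
The collision/streaming kernels sustain roughly 45 steps/s at 48³ on one
core.

## Known limitations

* BGK collision only; no MRT/TRT regularization, so very low viscosities
  (ω_f → 2) are out of reach.
* Stair-step walls (no interpolated bounce-back): wall placement is
  voxel-accurate only; curved-surface benchmarks would show first-order
  geometric error even though the flat-wall scheme is second order.
* Free outlets anchor the density exactly; physiological impedance
  (windkessel-type) outlets are not modeled.
* The scalar inlet pins `C_b` through an equilibrium distribution, which
  is first-order accurate at the port plane.
* Segmentation is 2-D-per-slice by design; strongly oblique structures
  thinner than the slice spacing can be missed between slices.
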