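# Methods

## Model

`softpbd` simulates deformable bodies — the target application is
soft-tissue deformation in virtual-surgery settings — as systems of point
masses coupled by two complementary mechanisms:

1. **Nonlinear viscoelastic mass-spring-dampers** supply the material's
   time-dependent response.  Each unique mesh edge carries a spring whose
   scalar force is cubic in the elongation `dl` below a crossover `dl_c`
   and linear above it, with value and slope continuous at the join:

       f(dl) = k1*dl + k2*dl^3                         |dl| <= dl_c
       f(dl) = (A + B*(|dl| - dl_c)) * sign(dl)        |dl| >  dl_c
       A = k1*dl_c + k2*dl_c^3,  B = k1 + 3*k2*dl_c^2

   Each node additionally carries a damper whose coefficient grows with
   the node's distance from its rest position,
   `f = -(b0 + b1*||x - x0||)*v`.  This displacement-anchored damping is
   what produces creep under constant load and stress relaxation under
   constant displacement: strongly displaced regions move slowly toward
   equilibrium, lightly displaced regions respond quickly.

2. **Compliant position-based constraints (XPBD)** supply
   incompressibility, strain limiting, contact response and stability.
   Each constraint is a scalar function `C(x)` with compliance `alpha`
   and an accumulated multiplier `lam` (reset each step); projection uses
   the canonical update

       dlam = -(C + at*lam) / (sum_k w_k |grad_k C|^2 + at),  at = alpha/dt^2

   applied Gauss-Seidel style, in insertion order, each projection seeing
   the latest positions.  `alpha = 0` recovers classical PBD; `alpha > 0`
   decouples effective stiffness from the iteration count and timestep.

Constraint types: distance, per-tetrahedron volume (solid, "entity"
organs — liver-like), global closed-surface volume by the divergence
theorem with the 1/6 normalization so the reference is a true geometric
volume (hollow, "cavity" organs — gallbladder-like), a unilateral
overstretch/compression band `|dl| <= k_ratio*l0` that suppresses local
superelasticity near load points, and unilateral contacts (sphere-sphere
as a distance constraint; sphere-triangle as a face-plane distance with
barycentrically weighted triangle gradients, exact normal derivatives
available as an option for verification).

## Time integration

One step: evaluate spring + external forces on the current state; predict
`x* = x + s*((x - x_prev) + w*f*dt^2)` (Verlet form); apply kinematic
boundary conditions; detect collisions on the predicted state and emit
zero-compliance contacts; reset multipliers; run the Gauss-Seidel loop
(`iterations` sweeps: persistent limiters and tet-volume constraints, then
the global surface-volume constraint, then contacts); commit and set
`v = (x_new - x_old)/dt`.

**Implicit damper.**  The damper is integrated by backward Euler: the
factor `s = 1/(1 + w*(b0 + b1*d)*dt)` multiplies both the inertial term
and the force increment, i.e. `v+ = (v + w*f*dt)/(1 + w*b*dt)`.  Two
properties motivated this over an explicit damper force: it is stable for
arbitrarily large damping (with `b1` in the thousands, explicit damping
impulses exceed the stability bound by orders of magnitude at any
practical timestep), and it reproduces the overdamped limit `v = f/b`
exactly at any timestep, which the rheometry experiments rely on — with
the factor applied to the inertia alone, the force increment bypasses the
damper at coarse timesteps and the creep curves lose their separation in
`b1`.

**Verlet bootstrap.**  `prime_state` sets
`x_prev = x - v*dt + (1/2) w f dt^2` so a run whose initial velocity or
acceleration matters starts with second-order accuracy (free fall is then
exact rather than accurate to O(dt/t)).

## Units and parameters

Positions in mm, time in s, mass in g; forces therefore in uN and gravity
9810 mm/s^2.  Node masses are a uniform lumping of
`density * rest volume` with density 1e-3 g/mm^3 (water-like).  Material
defaults: `k1 = 0.25`, `k2 = 10`, `b0 = 2`, `b1 = 1000`, `alpha = 0` —
the parameter set of the bundled nonlinearity experiment.  `dl_c`
defaults to 0.1 x the spring's rest length (fractional, so the cubic
regime scales with spring size on heterogeneous meshes; an absolute value
can be configured).  `k_ratio` defaults to 0.5; the overstretch band is
symmetric in stretch and compression.  Solver defaults `dt = 0.005 s`,
`iterations = 10`.

## Geometry

Cube and beam lattices use the 5-tets-per-cell split with alternating
mirror parity, which is conforming (neighbouring cells agree on face
diagonals) and partitions the box exactly; generated icospheres provide
closed surfaces whose enclosed volume converges to the sphere volume.
OBJ/OFF surface meshes are read and written through trimesh; TetGen
`.node`/`.ele` files through a small built-in reader (1-based on disk,
0-based in memory).

## Collision

Broad phase: AABBs hashed into buckets by the three-prime XOR hash
`((i*73856093) ^ (j*19349663) ^ (k*83492791)) mod table_size` over the
integer grid cells each box overlaps; every unordered pair is examined at
most once (a tested-pair memo), pairs sharing a node are excluded, and an
explicit AABB overlap re-check makes the output equal to brute-force
all-pairs intersection.  Narrow phase requires strict penetration; vertex
contacts fire only when the sphere centre projects inside the triangle
face.  Contacts are regenerated from the predicted positions every step
and projected last, with compliance 0, so committed states show no
measurable resting penetration.  Sphere-sphere tests between spheres of
the same body are off by default (self-collision is configurable).

## Experiments and their design choices

All experiments run on generated primitives; none needs external data.
The rheometry cube (60 mm edge, six cells per direction, base fixed, test
point at the exact centre of the upper face — division counts must be
even) carries springs and overstretch limiters but no volume constraints:
the tetrahedral incompressibility reaction at the test point is
independent of `b1` and an order of magnitude larger than the spring
forces, so with volume constraints on it masks exactly the viscoelastic
signatures the scenario measures.  The stability scenario keeps the full
constraint set, since constraint stabilization is what it tests.

* **Nonlinearity** (constant-velocity indentation, velocities 5/10/20
  mm/s): the reaction force at the driven node is reported as
  `m*a - (f_spring + f_damper + f_constraint + f_external)` with the
  constraint force reconstructed from the accumulated multipliers,
  `sum_c lam_c grad_c C / dt^2`.  Faster driving needs pointwise larger
  force (the damper term is linear in the velocity), and the
  quasi-static slope grows with displacement in the cubic regime before
  the overstretch limiters flatten the curve.
* **Creep** (constant load, `k1 = 0.05`, `b1` in {250, 1000, 4000}): the
  600 uN load is chosen so the spring network carries it inside the
  overstretch band — a load beyond the springs' clamped capacity (about
  1.3 mN at the test node) would hang on the rigid limiters and has no
  elastic plateau.  Displacement at fixed time orders inversely in `b1`;
  all curves approach a common elastic plateau (the damper carries no
  force at steady state).  Because the cubic material is very soft at
  small strains, the `b1 = 4000` curve settles over ~3e4 simulated
  seconds; each curve is integrated at dt = 0.04 s (checked against
  finer steps in the overdamped regime) until its per-200 s change falls
  below 2.5e-4 relative.
* **Stress relaxation** (ramp 20 mm in 0.5 s, hold 2 s, `k1 = 1`,
  `alpha = 0`): the smoothed (0.1 s moving average) holding force decays
  after the ramp; the relative decay orders inversely in `b1`.
* **Volume preservation**: a 60x20x20 mm cantilever (one end fixed) sags
  under gravity with hard per-tet constraints; an icosphere shell with
  one global surface-volume constraint falls onto a two-triangle floor.
  Both use a lightly damped material (`b1 = 0`) so the bodies actually
  move within the measurement window.  "Constraints off" removes the
  volume constraints only — springs, limiters and contacts remain — so
  the contrast isolates the volume constraint.
* **Stability / recovery**: every node above the fixed base is
  kinematically crushed to 20% height, held 0.2 s, released; the report
  tracks the maximum node deviation from rest.  The scenario material is
  `k1 = 1, k2 = 10, b0 = 2, b1 = 0` with gravity off: the `b1` damper is
  anchored to the rest position and would freeze the very return motion
  being measured, and gravity would make the weak-spring equilibrium a
  sagged shape rather than the rest shape.  The default window is 20 s:
  the edge-spring lattice has soft, nearly inextensional corner modes
  (restoring force second order in displacement) whose settling
  dominates the tail of the recovery; within 5 s the deviation is still
  5-10% of the edge length and sensitive to timestep and iteration
  count, while by 20 s it is robustly ~3%.  The pure-MSD twin (all
  constraints disabled) fails to recover (deviation an order of
  magnitude larger or divergence), reproducing the integrated-vs-MSD
  contrast.
* **Q statistic**: `Q = sum_i |p_model,i - p_ref,i|` compares matched
  node sets between two model variants (the runners' mode switch —
  `integrated`, `pbd_only`, `msd_only` — produces the variants); no
  finite-element baseline is bundled.

## What the synthetic scenarios do and do not show

The generated geometry is exact and regular: lattices are conforming and
error-free, loads are single-node, and materials are homogeneous.
Passing tests therefore demonstrate the correctness of the constraint
mathematics, the integrator's limits, and the qualitative viscoelastic
phenomenology — not anatomical fidelity, heterogeneous material response,
mesh-quality robustness, or interactive frame rates.  The damper's
anchoring to absolute rest positions means a freely translating body is
damped against the world frame; momentum-conservation checks therefore
run with the dampers off.

## Numerical choices and degenerate inputs

Springs and constraint pairs shorter than 1e-9 mm are skipped with a
warning; degenerate triangles likewise.  Coincident sphere centres in a
contact are separated along +x by a nominal offset before projection.
Constraints whose nodes are all fixed under zero compliance are skipped.
A non-finite force or position raises a solver error naming the node
(positions attach the last good state).  The Gauss-Seidel hot loop and
the spring accumulation are numba-compiled; both are cross-checked
against pure-numpy reference implementations in the test suite, and the
scalar spring law is written so it is exactly odd in the elongation.

## Known limitations

Hard per-tet volume constraints volumetrically lock coarse lattices
(more projection iterations can slow shape recovery); a small `alpha`
relieves this at the cost of exactness.  Strain-limiting bands make the
statics insensitive to spring parameters once loads exceed the springs'
clamped capacity.  No continuous collision detection, friction, or
self-collision by default; no bending stiffness, so thin-shell dynamics
are governed by the in-surface spring network alone.
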