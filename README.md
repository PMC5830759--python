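# softpbd

Soft-body simulation for virtual-surgery-style soft-tissue deformation:
**nonlinear viscoelastic mass-spring-dampers** integrated with
**compliant position-based constraint projection (XPBD)**.

Surgical simulators need deformation models that are simultaneously fast,
unconditionally stable, and faithful to the signature behaviours of soft
tissue — nonlinear stiffening, creep, stress relaxation, and
incompressibility.  Classical mass-spring-damper (MSD) models capture the
time-dependent material response but explode under large deformation;
classical position-based dynamics (PBD) is unconditionally stable but has
no force or time semantics, so viscoelasticity cannot be expressed.
`softpbd` combines the two: springs and dampers act as forces in a
Verlet-style position predictor, and the predicted positions are then
corrected by Gauss-Seidel projection of compliant constraints.

The spring on each mesh edge is cubic below a crossover elongation and
linear above it, C¹ at the join:

    f(dl) = k1·dl + k2·dl³                       |dl| ≤ dl_c
    f(dl) = (A + B(|dl| − dl_c))·sgn(dl)         |dl| > dl_c
    A = k1·dl_c + k2·dl_c³,   B = k1 + 3k2·dl_c²

each node carries a damper `f = −(b0 + b1‖x − x₀‖)·v` (integrated
implicitly for unconditional stability), and each constraint `C(x)` with
compliance α is projected by the XPBD update

    Δλ = −(C + α̃λ) / (Σ w‖∇C‖² + α̃),   α̃ = α/Δt²

Constraint types: distance, per-tetrahedron volume (solid organs), global
closed-surface volume (hollow organs), unilateral overstretch/compression
limiting, and sphere/triangle contacts fed by a spatial-hash broad phase.

Units: mm / g / s (forces in µN, gravity 9810 mm/s²).

## Worked example

Drop a hollow icosphere shell (radius 15 mm, one global volume
constraint) onto a rigid floor and watch the enclosed volume:

```python
import numpy as np
from softpbd.experiments import run_volume_tests

on  = run_volume_tests("falling_cavity", volume_constraints=True)
off = run_volume_tests("falling_cavity", volume_constraints=False)
print(f"max |V/V0 - 1| with the volume constraint:    {on['max_drift']:.4f}")
print(f"max |V/V0 - 1| without the volume constraint: {off['max_drift']:.4f}")
```

prints

```
max |V/V0 - 1| with the volume constraint:    0.0018
max |V/V0 - 1| without the volume constraint: 1.0000
```

— with the constraint the shell's volume never deviates more than 0.2%
while it falls, impacts and rests; without it the contact squashes the
shell flat (the volume ratio collapses, drifting by 100%).

The bundled experiments are also available on the command line:

```sh
softpbd experiment nonlinearity --out out/nl       # force-displacement curves
softpbd experiment creep --out out/creep           # displacement-time curves
softpbd experiment stress-relaxation --out out/sr  # force-time curves
softpbd experiment volume --which cantilever --out out/vol
softpbd experiment stability --out out/stab        # crush-and-release recovery
softpbd simulate scenario.yaml --out out/sim       # arbitrary YAML scenario
```

Each writes CSV time series plus a `summary.json` with the scenario's
qualitative checks (velocity ordering, creep plateau spread, relaxation
decays, volume drifts, recovery state).

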