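"""Scripted rheometry, volume-preservation and stability scenarios.

All scenarios run on parameterized primitive geometry generated by
:mod:`softpbd.geometry`:

* the 60 mm cube (6 cells per direction) with its base fixed and the
  centre node of the upper face as the driven/loaded *test point* — used
  for the nonlinearity, creep and stress-relaxation tests;
* a 60 x 20 x 20 mm cantilever beam sagging under gravity — local
  (tetrahedral) volume preservation;
* an icosphere shell dropped onto a plane — global (closed-surface)
  volume preservation of a hollow body;
* the crushed-and-released cube — stability / shape recovery.

Every runner is deterministic under a fixed configuration and accepts a
``mode`` switch (``integrated`` / ``pbd_only`` / ``msd_only``) so the
integrated model can be contrasted with its classical limits on the same
mesh.  The qualitative viscoelastic behaviours (force rises with loading
velocity, creep slows with b1, relaxation decays faster for small b1) are
exposed as orderings on the sampled curves, not as curve-value matches.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .forces import MaterialParams
from .geometry import (build_model, face_nodes, generate_beam,
                       generate_cube_lattice, generate_icosphere,
                       top_center_node)
from .solver import BoundaryCondition, ScenarioResult, SolverConfig, run
from .constraints import KIND_TET_VOLUME

__all__ = [
    "cube_scenario", "falling_cavity_model", "run_nonlinearity", "run_creep",
    "run_stress_relaxation", "run_volume_tests", "run_stability",
    "q_statistic", "smooth_series",
]

#: Standard gravity in the package's mm/g/s unit system (mm/s^2).
GRAVITY = 9810.0

#: Cube rheometry geometry: 60 mm edge, six cells per direction.
CUBE_EDGE = 60.0
CUBE_DIVISIONS = 6

#: Constant load used by the creep test (uN).  Chosen once so the load is
#: carried by the spring network inside the overstretch band (the elastic
#: range of the creep material k1=0.05, k2=10): a load much beyond the
#: springs' clamped capacity would hang on the rigid limiters and turn the
#: scenario into a strain-limit test with no elastic plateau.
CREEP_FORCE = 600.0


def cube_scenario(material: MaterialParams, edge: float = CUBE_EDGE,
                  divisions: int = CUBE_DIVISIONS, mode: str = "integrated",
                  volume_constraints: bool = False):
    """Cube model with fixed base; returns ``(model, test_node_index)``.

    ``divisions`` must be even so the upper face has an exact centre node.
    The rheometry scenarios probe the spring/damper law, so by default the
    cube carries springs and overstretch limiters but no tetrahedral
    volume constraints (whose b1-independent reaction would mask the
    viscoelastic response at the test point); pass
    ``volume_constraints=True`` for the stability scenario, which relies
    on the full constraint set.
    """
    mesh = generate_cube_lattice(edge, divisions)
    model = build_model(mesh, material)
    if not volume_constraints:
        model.batch = model.batch.without_kinds([KIND_TET_VOLUME])
    model.mode = mode
    model.bcs.append(BoundaryCondition("fixed", face_nodes(mesh, 2, "min")))
    return model, top_center_node(mesh)


def run_nonlinearity(velocities=(5.0, 10.0, 20.0), max_displacement=25.0,
                     material: MaterialParams | None = None,
                     dt: float = 0.005, iterations: int = 10,
                     mode: str = "integrated", sample_every: int = 1):
    """Constant-velocity indentation: force-displacement curve per velocity.

    The test point is driven into the cube perpendicular to the upper
    face; the reaction force needed to sustain the drive is sampled
    against the test point's displacement.  Default material is the
    nonlinearity-figure set (k1=0.25, k2=10, b0=2, b1=1000).
    """
    if material is None:
        material = MaterialParams(k1=0.25, k2=10.0, b0=2.0, b1=1000.0,
                                  alpha=0.0)
    cfg = SolverConfig(dt=dt, iterations=iterations)
    down = np.array([0.0, 0.0, -1.0])
    curves = {}
    for v in velocities:
        model, test = cube_scenario(material, mode=mode)
        model.bcs.append(BoundaryCondition("prescribed_velocity", [test],
                                           value=v * down))
        res = run(model, cfg, duration=max_displacement / v if v > 0 else 0.0,
                  probes=[("displacement", test, down),
                          ("reaction_force", test, down)],
                  probe_names=["displacement", "force"],
                  sample_every=sample_every)
        curves[float(v)] = res
    return {"curves": curves,
            "metadata": {"velocities": list(map(float, velocities)),
                         "max_displacement": max_displacement,
                         "material": vars(material).copy(), "dt": dt,
                         "iterations": iterations, "mode": mode}}


def run_creep(b1_values=(250.0, 1000.0, 4000.0), force: float = CREEP_FORCE,
              material: MaterialParams | None = None, dt: float = 0.04,
              iterations: int = 10, fine_duration: float = 2.0,
              max_duration: float = 40000.0, chunk: float = 200.0,
              settle_tol: float = 2.5e-4, mode: str = "integrated"):
    """Constant-force creep: displacement-time curve per damping value b1.

    A constant load is applied to the test point perpendicular to the
    upper face.  Displacement grows toward an elastic plateau that is
    independent of b1 (at steady state the damper carries no force); the
    approach slows as b1 grows.  Each curve is integrated until quiescent
    (relative displacement change below ``settle_tol`` per chunk) or
    ``max_duration``, whichever comes first.  Default material is the
    creep-figure set (k1=0.05, k2=10, b0=2); with its soft cubic springs
    the largest damping value settles over tens of thousands of simulated
    seconds, so the default timestep is the coarse overdamped-regime
    0.04 s (checked against finer steps) and sampling thins out after the
    fine-resolution opening window.
    """
    if material is None:
        material = MaterialParams(k1=0.05, k2=10.0, b0=2.0, alpha=0.0)
    cfg = SolverConfig(dt=dt, iterations=iterations)
    down = np.array([0.0, 0.0, -1.0])
    curves, plateaus = {}, {}
    for b1 in b1_values:
        mat = material.with_(b1=float(b1))
        model, test = cube_scenario(mat, mode=mode)
        model.bcs.append(BoundaryCondition("applied_force", [test],
                                           value=force * down))
        probes = [("displacement", test, down)]
        res = run(model, cfg, duration=fine_duration, probes=probes,
                  probe_names=["displacement"], sample_every=1)
        t_all = [res.time]
        d_all = [res["displacement"]]
        t = fine_duration
        prev = d_all[-1][-1]
        while t < max_duration:
            res = run(model, cfg, duration=chunk, probes=probes,
                      probe_names=["displacement"], t0=t,
                      sample_every=max(1, int(round(1.0 / dt))))
            t_all.append(res.time)
            d_all.append(res["displacement"])
            t += chunk
            cur = d_all[-1][-1]
            if abs(cur - prev) <= settle_tol * max(abs(cur), 1e-12):
                break
            prev = cur
        tt = np.concatenate(t_all)
        dd = np.concatenate(d_all)
        curves[float(b1)] = ScenarioResult(
            time=tt, series={"displacement": dd},
            metadata={"b1": float(b1), "force": force})
        plateaus[float(b1)] = float(dd[-1])
    return {"curves": curves, "plateaus": plateaus,
            "metadata": {"force": force, "material": vars(material).copy(),
                         "dt": dt, "iterations": iterations, "mode": mode,
                         "settle_tol": settle_tol,
                         "max_duration": max_duration}}


def run_stress_relaxation(b1_values=(250.0, 1000.0, 4000.0),
                          displacement: float = 20.0,
                          ramp_time: float = 0.5, hold_time: float = 2.0,
                          material: MaterialParams | None = None,
                          dt: float = 0.005, iterations: int = 10,
                          mode: str = "integrated"):
    """Stress relaxation: force-time curve per b1 during a fixed hold.

    The test point is rammed down by ``displacement`` over ``ramp_time``,
    then held fixed while its reaction force is sampled for ``hold_time``.
    Default material is the relaxation-figure set (k1=1, k2=10, b0=2,
    alpha=0).
    """
    if material is None:
        material = MaterialParams(k1=1.0, k2=10.0, b0=2.0, alpha=0.0)
    cfg = SolverConfig(dt=dt, iterations=iterations)
    down = np.array([0.0, 0.0, -1.0])
    v = displacement / ramp_time
    curves = {}
    for b1 in b1_values:
        mat = material.with_(b1=float(b1))
        model, test = cube_scenario(mat, mode=mode)
        bc = BoundaryCondition("prescribed_velocity", [test], value=v * down,
                               schedule=(0.0, ramp_time))
        hold = BoundaryCondition("prescribed_velocity", [test],
                                 value=np.zeros(3),
                                 schedule=(ramp_time, np.inf))
        model.bcs += [bc, hold]
        run(model, cfg, duration=ramp_time, probes=[])
        res = run(model, cfg, duration=hold_time, t0=ramp_time,
                  probes=[("reaction_force", test, down)],
                  probe_names=["force"], sample_every=1)
        curves[float(b1)] = res
    return {"curves": curves,
            "metadata": {"displacement": displacement,
                         "ramp_time": ramp_time, "hold_time": hold_time,
                         "material": vars(material).copy(), "dt": dt,
                         "iterations": iterations, "mode": mode}}


def falling_cavity_model(material: MaterialParams | None = None,
                         radius: float = 15.0, subdivisions: int = 2,
                         drop: float = 5.0):
    """Icosphere shell above a rigid floor, ready to drop.

    All surface vertices carry collision spheres of radius 0.3 x the
    shortest surface edge (small enough that the resting shell has no
    self-contacts); the floor is two large fixed triangles at z = 0.
    Returns ``(model, sphere_radius)``.
    """
    if material is None:
        material = MaterialParams(k1=0.25, k2=10.0, b0=2.0, b1=0.0,
                                  alpha=0.0)
    from .collision import CollisionSpec, floor_triangles

    mesh = generate_icosphere(radius, subdivisions)
    mesh.vertices[:, 2] += radius + drop
    model = build_model(mesh, material)
    pos, faces = floor_triangles(z=0.0, half_extent=3.0 * radius)
    static = model.add_static_nodes(pos)
    sphere_r = 0.3 * float(model.springs.l0.min())
    model.collision = CollisionSpec(
        sphere_nodes=np.arange(len(mesh.vertices)),
        sphere_radii=sphere_r,
        triangles=static[faces],
        cell_size=4.0 * sphere_r,
        margin=sphere_r)
    return model, sphere_r


def run_volume_tests(which: str, volume_constraints: bool = True,
                     material: MaterialParams | None = None,
                     dt: float = 0.005, iterations: int = 10,
                     duration: float | None = None):
    """Volume-preservation scenarios; returns the V(t)/V(0) ratio series.

    ``which = "cantilever"``: a 60x20x20 mm beam, one end fixed, sags
    under gravity with per-tetrahedron volume constraints.
    ``which = "falling_cavity"``: an icosphere shell with a single global
    enclosed-volume constraint falls onto a plane and is squashed by the
    contact.  ``volume_constraints=False`` removes the volume constraints
    only (springs, overstretch limiters and — for the falling shell —
    contacts remain), giving the unconstrained contrast run.

    Both scenarios use a lightly damped material (b1 = 0): the experiment
    probes the constraints under large motion within a short window, which
    a strong world-anchored viscoelastic damper would suppress.
    """
    if material is None:
        material = MaterialParams(k1=0.25, k2=10.0, b0=2.0, b1=0.0, alpha=0.0)
    cfg = SolverConfig(dt=dt, iterations=iterations,
                       gravity=(0.0, 0.0, -GRAVITY))
    if which == "cantilever":
        duration = 1.0 if duration is None else duration
        mesh = generate_beam((60.0, 20.0, 20.0), (6, 2, 2))
        model = build_model(mesh, material)
        model.bcs.append(BoundaryCondition("fixed", face_nodes(mesh, 0, "min")))
    elif which == "falling_cavity":
        duration = 1.5 if duration is None else duration
        model, _ = falling_cavity_model(material)
    else:
        raise InvalidArgumentError(f"unknown volume test {which!r}")

    if not volume_constraints:
        model.batch = model.batch.without_kinds([KIND_TET_VOLUME])
        model.surface_volume = None

    v0 = model.current_volume()
    from .errors import SolverError

    try:
        res = run(model, cfg, duration=duration, probes=[("volume",)],
                  probe_names=["volume"], sample_every=1)
        ratio = res["volume"] / v0
        time = res.time
        diverged = False
    except SolverError:
        time = np.array([duration])
        ratio = np.array([np.inf])
        diverged = True
    result = ScenarioResult(time=time, series={"volume_ratio": ratio},
                            metadata={"which": which, "v0": v0,
                                      "volume_constraints": volume_constraints,
                                      "material": vars(material).copy(),
                                      "dt": dt, "iterations": iterations,
                                      "diverged": diverged})
    max_drift = float(np.max(np.abs(ratio - 1.0)))
    return {"result": result, "max_drift": max_drift, "diverged": diverged}


def run_stability(material: MaterialParams | None = None,
                  crush_factor: float = 0.2, hold_time: float = 0.2,
                  recovery_time: float = 20.0, dt: float = 0.005,
                  iterations: int = 10, edge: float = CUBE_EDGE,
                  divisions: int = CUBE_DIVISIONS,
                  mode: str = "integrated", sample_every: int = 10):
    """Crush-and-release recovery test.

    Every node above the fixed base is kinematically squashed to
    ``crush_factor`` of its rest height (far past the overstretch band),
    held, then released.  The report tracks the maximum node deviation
    from the rest shape over time; the model *recovers* if the final
    deviation is below 5% of the edge length with no divergence.  Gravity
    is off and the damper is the baseline b0 only: the test probes elastic
    shape memory and constraint stabilization, not viscous time scales
    (the displacement-anchored b1 term would freeze the return motion it
    is supposed to be measured against).  The default window of 20 s
    covers the slow settling of the lattice's soft corner modes, whose
    restoring force is second order in displacement.  Divergence
    (non-finite positions, typical for the pure-MSD mode) is a reported
    outcome, not an exception.
    """
    if material is None:
        material = MaterialParams(k1=1.0, k2=10.0, b0=2.0, b1=0.0, alpha=0.0)
    from .errors import SolverError

    cfg = SolverConfig(dt=dt, iterations=iterations)
    model, _ = cube_scenario(material, edge=edge, divisions=divisions,
                             mode=mode, volume_constraints=True)
    mesh = model.mesh
    base = face_nodes(mesh, 2, "min")
    crushed = np.setdiff1d(np.arange(len(mesh.vertices)), base)
    zmin = mesh.vertices[:, 2].min()
    targets = mesh.vertices[crushed].copy()
    targets[:, 2] = zmin + crush_factor * (targets[:, 2] - zmin)
    model.bcs.append(BoundaryCondition("prescribed_displacement", crushed,
                                       schedule=(0.0, hold_time),
                                       targets=targets))
    probes = [("max_deviation",)]
    diverged = False
    try:
        r1 = run(model, cfg, duration=hold_time, probes=probes,
                 probe_names=["max_deviation"], sample_every=sample_every)
        r2 = run(model, cfg, duration=recovery_time, t0=hold_time,
                 probes=probes, probe_names=["max_deviation"],
                 sample_every=sample_every)
        time = np.concatenate([r1.time, r2.time])
        dev = np.concatenate([r1["max_deviation"], r2["max_deviation"]])
        final_dev = float(dev[-1])
    except SolverError:
        diverged = True
        time = np.array([hold_time + recovery_time])
        dev = np.array([np.inf])
        final_dev = np.inf
    recovered = (not diverged) and final_dev < 0.05 * edge
    return {"recovered": recovered, "diverged": diverged,
            "final_deviation": final_dev,
            "deviation": ScenarioResult(time=time,
                                        series={"max_deviation": dev}),
            "metadata": {"crush_factor": crush_factor,
                         "hold_time": hold_time,
                         "recovery_time": recovery_time, "dt": dt,
                         "iterations": iterations, "edge": edge,
                         "mode": mode,
                         "material": vars(material).copy()}}


def q_statistic(positions_model, positions_reference) -> float:
    """Whole-surface node-distance statistic Q = sum_i |p_model,i - p_ref,i|.

    Symmetric in its arguments; requires matched node indexing.
    """
    a = np.asarray(positions_model, float)
    b = np.asarray(positions_reference, float)
    if a.shape != b.shape:
        raise InvalidArgumentError(
            f"position sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, axis=-1).sum())


def smooth_series(t, y, window: float = 0.1):
    """Centred moving average over a time window (oscillation-tolerant).

    Assumes uniform sampling; the window is rounded to an odd number of
    samples.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 2:
        return y.copy()
    dt = t[1] - t[0]
    half = max(int(round(window / dt / 2.0)), 0)
    n = 2 * half + 1
    pad = np.pad(y, half, mode="edge")
    kernel = np.ones(n) / n
    return np.convolve(pad, kernel, mode="valid")
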