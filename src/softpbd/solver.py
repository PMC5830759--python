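"""Timestepping: force evaluation, position prediction, constraint projection.

One step of the integrated method:

1. evaluate nonlinear spring forces and external loads;
2. predict positions with a Verlet-style update
   ``x* = x + s * ((x - x_prev) + w * f * dt^2)``, where ``s`` integrates
   the viscoelastic damper implicitly (see below);
3. apply kinematic boundary conditions (fixed / prescribed nodes, w = 0);
4. detect collisions on the predicted state and generate contact
   constraints with compliance 0;
5. reset multipliers and run the Gauss-Seidel projection loop over all
   active constraints (persistent limiters and volume constraints first,
   the global surface-volume constraint between sweeps, fresh contacts
   last);
6. commit positions and recompute velocities ``v = (x^{n+1} - x^n)/dt``.

Implicit damper.  The damper law ``f = -(b0 + b1*||x - x0||) * v`` is
integrated by backward Euler: the per-step velocity update
``v+ = (v + w*f*dt) / (1 + w*b*dt)`` is realized by scaling both the
inertial term and the force increment with
``s = 1 / (1 + w*(b0 + b1*d)*dt)``.  This equals the explicit damper force
to first order in ``b*dt``, reproduces the overdamped limit ``v = f/b``
exactly at any timestep, and remains stable for arbitrarily large
damping — with mm-scale displacements and the damping coefficients the
rheometry scenarios use (b1 up to thousands), an explicit damping impulse
exceeds the stability bound by orders of magnitude at every practical
timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import accumulate_spring_forces, gauss_seidel_sweep
from .constraints import project_surface_volume
from .errors import InvalidArgumentError, SolverError
from .forces import damping_coefficients, spring_forces

__all__ = [
    "SolverConfig", "BoundaryCondition", "StepDiagnostics", "ScenarioResult",
    "predict_positions", "step", "run",
]


@dataclass
class SolverConfig:
    """Timestep (s), Gauss-Seidel iteration count and gravity (mm/s^2)."""

    dt: float = 0.005
    iterations: int = 10
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    max_substeps: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.iterations < 1:
            raise InvalidArgumentError("iterations must be >= 1")
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)


@dataclass
class BoundaryCondition:
    """Kinematic or force boundary condition on a node set.

    kinds:
      * ``fixed`` — w = 0, node holds its current position;
      * ``prescribed_velocity`` — w = 0, node moves by ``value * dt`` each
        step (the §-style constant displacement velocity drive);
      * ``prescribed_displacement`` — w = 0, node pinned at rest position
        + ``value`` (or at per-node absolute ``targets`` if given);
      * ``applied_force`` — ``value`` (uN) added to the node's external
        force.

    ``schedule = (t0, t1)`` limits the condition to ``t0 <= t < t1``;
    ``None`` means always active.
    """

    kind: str
    node_ids: np.ndarray
    value: np.ndarray = field(default_factory=lambda: np.zeros(3))
    schedule: tuple | None = None
    targets: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("fixed", "prescribed_velocity",
                             "prescribed_displacement", "applied_force"):
            raise InvalidArgumentError(f"unknown BC kind {self.kind!r}")
        self.node_ids = np.atleast_1d(np.asarray(self.node_ids, dtype=np.int64))
        self.value = np.asarray(self.value, dtype=float).reshape(3)
        if self.targets is not None:
            self.targets = np.asarray(self.targets, float).reshape(
                len(self.node_ids), 3)

    def active(self, t: float) -> bool:
        if self.schedule is None:
            return True
        t0, t1 = self.schedule
        return t0 <= t < t1


@dataclass
class StepDiagnostics:
    """Per-step report: constraint residual, contacts, kinetic energy."""

    max_C: float = 0.0
    n_contacts: int = 0
    kinetic_energy: float = 0.0
    contacts: object = None


def predict_positions(system, forces, dt: float, damping_scale=None, w=None):
    """Verlet-form predictor ``x* = x + s*((x - x_prev) + w*f*dt^2)``.

    ``damping_scale`` is the per-node implicit damper factor (default 1);
    ``w`` overrides the system's inverse masses (used when boundary
    conditions temporarily pin nodes).  Non-finite forces raise
    :class:`SolverError` naming the offending node.
    """
    forces = np.asarray(forces, float)
    bad = ~np.isfinite(forces).all(axis=1)
    if bad.any():
        raise SolverError("non-finite force", node=int(np.flatnonzero(bad)[0]))
    if w is None:
        w = system.w
    s = 1.0 if damping_scale is None else np.asarray(damping_scale)[:, None]
    x_star = system.x + s * ((system.x - system.x_prev)
                             + (w[:, None] * dt * dt) * forces)
    x_star[w == 0.0] = system.x[w == 0.0]
    return x_star


def prime_state(model, cfg: SolverConfig, t: float = 0.0) -> None:
    """Second-order Verlet bootstrap of ``x_prev`` from the current state.

    Sets ``x_prev = x - v*dt + (1/2) w f dt^2`` so the first step carries
    the current velocity and half the current acceleration — the standard
    leapfrog start, which makes e.g. ballistic trajectories exact rather
    than accurate to O(dt/t).  Call once before a run whose initial
    velocity matters.
    """
    s = model.system
    f = external_forces(model, cfg, t)
    if model.springs_enabled and len(model.springs):
        f = f + spring_forces(s, model.springs, model.material, dl_c=model.dl_c)
    s.x_prev = s.x - s.v * cfg.dt + 0.5 * (s.w[:, None] * cfg.dt ** 2) * f


def _effective_w(model, t: float):
    w = model.system.w.copy()
    for bc in model.bcs:
        if bc.kind != "applied_force" and bc.active(t):
            w[bc.node_ids] = 0.0
    return w


def external_forces(model, cfg: SolverConfig, t: float) -> np.ndarray:
    """Gravity plus active applied-force boundary conditions (uN)."""
    m = model.system.masses()
    f = m[:, None] * cfg.gravity[None, :]
    for bc in model.bcs:
        if bc.kind == "applied_force" and bc.active(t):
            f[bc.node_ids] += bc.value
    return f


def step(model, cfg: SolverConfig, t: float = 0.0,
         compute_residual: bool = False) -> StepDiagnostics:
    """Advance the model by one timestep starting at time ``t``.

    Updates ``model.system`` in place and returns diagnostics.  Raises
    :class:`SolverError` (with the last good state attached) if positions
    become non-finite.
    """
    system = model.system
    dt = cfg.dt
    w_eff = _effective_w(model, t)

    f = external_forces(model, cfg, t)
    scale = None
    if model.springs_enabled:
        if len(model.springs):
            accumulate_spring_forces(system.x, model.springs.i,
                                     model.springs.j, model.springs.l0,
                                     model.dl_c, model.material.k1,
                                     model.material.k2, f)
        b = damping_coefficients(system, model.material)
        scale = 1.0 / (1.0 + w_eff * b * dt)

    x_star = predict_positions(system, f, dt, damping_scale=scale, w=w_eff)

    for bc in model.bcs:
        if not bc.active(t):
            continue
        if bc.kind == "prescribed_velocity":
            x_star[bc.node_ids] = system.x[bc.node_ids] + bc.value * dt
        elif bc.kind == "prescribed_displacement":
            if bc.targets is not None:
                x_star[bc.node_ids] = bc.targets
            else:
                x_star[bc.node_ids] = system.x_rest[bc.node_ids] + bc.value

    contacts = None
    if model.constraints_enabled and model.collision is not None:
        from .collision import detect_contacts

        contacts = detect_contacts(x_star, model.collision)
        if len(contacts) == 0:
            contacts = None

    if model.constraints_enabled:
        batch = model.batch if len(model.batch) else None
        if batch is not None:
            batch.reset_lambdas()
            a = batch.arrays()
            alpha_t = a["alpha"] / (dt * dt)
        sv = model.surface_volume
        if sv is not None:
            sv.lam = 0.0
        if contacts is not None:
            ca = contacts.arrays()
            c_alpha_t = ca["alpha"] / (dt * dt)
        for _ in range(cfg.iterations):
            if batch is not None:
                gauss_seidel_sweep(x_star, w_eff, a["kind"], a["nodes"],
                                   a["rest"], a["aux"], alpha_t, a["lam"],
                                   a["unilateral"])
            if sv is not None:
                project_surface_volume(sv, x_star, w_eff, dt)
            if contacts is not None:
                gauss_seidel_sweep(x_star, w_eff, ca["kind"], ca["nodes"],
                                   ca["rest"], ca["aux"], c_alpha_t,
                                   ca["lam"], ca["unilateral"])

    if not np.isfinite(x_star).all():
        bad = int(np.flatnonzero(~np.isfinite(x_star).all(axis=1))[0])
        raise SolverError("non-finite position after projection", node=bad,
                          state=system.x.copy())

    system.x_prev = system.x
    system.x = x_star
    system.v = (system.x - system.x_prev) / dt

    diag = StepDiagnostics(
        n_contacts=0 if contacts is None else len(contacts),
        kinetic_energy=float(
            0.5 * (system.masses() * (system.v ** 2).sum(axis=1)).sum()),
        contacts=contacts,
    )
    if compute_residual and model.constraints_enabled:
        res = 0.0
        if len(model.batch):
            res = float(np.max(np.abs(model.batch.eval_all(system.x))),)
        if model.surface_volume is not None:
            res = max(res, abs(model.surface_volume.evaluate(system.x)[0]))
        if contacts is not None and len(contacts):
            res = max(res, float(np.max(np.abs(contacts.eval_all(system.x)))))
        diag.max_C = res
    return diag


@dataclass
class ScenarioResult:
    """Sampled time series from a scenario run.

    ``series`` maps probe names to arrays aligned with ``time``;
    ``metadata`` snapshots the configuration that produced them.
    """

    time: np.ndarray
    series: dict
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.series[key]

    @property
    def displacement(self):
        return self.series.get("displacement")

    @property
    def force(self):
        return self.series.get("force")

    @property
    def volume(self):
        return self.series.get("volume")

    def to_csv(self, path):
        """Write a deterministic CSV: header ``t,<series...>``, 17 sig digits."""
        keys = sorted(self.series)
        with open(path, "w", newline="\n") as fh:
            fh.write(",".join(["t"] + keys) + "\n")
            cols = [self.time] + [np.asarray(self.series[k]) for k in keys]
            for row in zip(*cols):
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


class _ReactionProbe:
    """Reaction force at a kinematically driven node.

    Defined as the force the driver must supply for the observed motion:
    ``F = m*a - (f_spring + f_damper + f_constraint + f_gravity +
    f_applied)`` with ``a`` the finite-difference acceleration of the
    node and ``f_constraint = sum_c lam_c grad_c C / dt^2`` the force
    interpretation of the accumulated multipliers.  Reported as the
    component along ``direction``.
    """

    def __init__(self, node, direction):
        self.node = int(node)
        self.direction = np.asarray(direction, float) / np.linalg.norm(direction)
        self._x_nn = None  # x^{n-1} before the last commit

    def __call__(self, model, cfg, t, diag):
        from .constraints import ConstraintBatch
        from .forces import damper_forces

        s = model.system
        i = self.node
        dt = cfg.dt
        x_nn = self._x_nn if self._x_nn is not None else s.x_prev
        a = (s.x[i] - 2.0 * s.x_prev[i] + x_nn[i]) / (dt * dt)
        m = s.masses()[i]

        f = external_forces(model, cfg, t)[i].copy()
        if model.springs_enabled and len(model.springs):
            f += spring_forces(s, model.springs, model.material,
                               dl_c=model.dl_c)[i]
            f += damper_forces(s, model.material)[i]
        if model.constraints_enabled:
            if len(model.batch):
                f += model.batch.constraint_forces_at(s.x, dt, only_node=i)
            sv = model.surface_volume
            if sv is not None and sv.lam != 0.0:
                _, g = sv.evaluate(s.x)
                f += sv.lam * g[i] / (dt * dt)
            if diag is not None and diag.contacts is not None:
                f += diag.contacts.constraint_forces_at(s.x, dt, only_node=i)
        return float((m * a - f) @ self.direction)

    def after_step(self, model):
        self._x_nn = model.system.x_prev


def _make_probe(spec):
    kind = spec[0]
    if kind == "displacement":
        _, node, direction = spec
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)

        def probe(model, cfg, t, diag, node=int(node), d=d):
            s = model.system
            return float((s.x[node] - s.x_rest[node]) @ d)
        return probe
    if kind == "node_position":
        _, node = spec

        def probe(model, cfg, t, diag, node=int(node)):
            return model.system.x[node].copy()
        return probe
    if kind == "reaction_force":
        _, node, direction = spec
        return _ReactionProbe(node, direction)
    if kind == "volume":
        return lambda model, cfg, t, diag: model.current_volume()
    if kind == "kinetic_energy":
        return lambda model, cfg, t, diag: diag.kinetic_energy
    if kind == "max_deviation":
        return lambda model, cfg, t, diag: float(np.max(np.linalg.norm(
            model.system.x - model.system.x_rest, axis=1)))
    if kind == "max_C":
        return lambda model, cfg, t, diag: diag.max_C
    raise InvalidArgumentError(f"unknown probe kind {kind!r}")


def run(model, cfg: SolverConfig, duration: float, probes=(),
        sample_every: int = 1, t0: float = 0.0,
        probe_names=None, trajectory=None,
        contact_log=None) -> ScenarioResult:
    """Advance ``model`` for ``duration`` seconds, sampling probes.

    ``probes`` is a sequence of probe specs, e.g. ``("displacement", node,
    direction)``, ``("reaction_force", node, direction)``, ``("volume",)``,
    ``("kinetic_energy",)``, ``("max_deviation",)``, ``("node_position",
    node)`` or ``("max_C",)``.  Samples are taken every ``sample_every``
    steps (and at the final step).  ``trajectory`` (a path) writes sampled
    per-frame node positions as long-format CSV ``t,node,x,y,z``;
    ``contact_log`` writes one CSV row per contact event per step
    (``t,kind,nodes,C``).  ``cfg.max_substeps > 1`` subdivides every step
    into that many solver substeps while keeping the sampling cadence.
    The run is deterministic: identical model + config produce
    bit-identical results.
    """
    if duration < 0:
        raise InvalidArgumentError("duration must be >= 0")
    if cfg.max_substeps > 1:
        sample_every = sample_every * cfg.max_substeps
        cfg = SolverConfig(dt=cfg.dt / cfg.max_substeps,
                           iterations=cfg.iterations, gravity=cfg.gravity,
                           max_substeps=1)
    n_steps = int(round(duration / cfg.dt))
    fns = [_make_probe(p) for p in probes]
    names = list(probe_names) if probe_names is not None else \
        [p[0] if isinstance(p, (tuple, list)) else str(p) for p in probes]
    if len(set(names)) != len(names):
        names = [f"{n}_{i}" for i, n in enumerate(names)]
    need_residual = any(n.startswith("max_C") for n in names)

    times, samples = [], {n: [] for n in names}
    traj_fh = open(trajectory, "w", newline="\n") if trajectory else None
    if traj_fh:
        traj_fh.write("t,node,x,y,z\n")
    log_fh = open(contact_log, "w", newline="\n") if contact_log else None
    if log_fh:
        log_fh.write("t,kind,nodes,C\n")
    t = t0
    try:
        for k in range(n_steps):
            diag = step(model, cfg, t=t, compute_residual=need_residual)
            t = t0 + (k + 1) * cfg.dt
            if (k + 1) % sample_every == 0 or k == n_steps - 1:
                times.append(t)
                for name, fn in zip(names, fns):
                    samples[name].append(fn(model, cfg, t, diag))
                if traj_fh:
                    for node, p in enumerate(model.system.x):
                        traj_fh.write(
                            f"{t:.9g},{node},{p[0]:.9g},{p[1]:.9g},"
                            f"{p[2]:.9g}\n")
            if log_fh and diag.contacts is not None and len(diag.contacts):
                C = diag.contacts.eval_all(model.system.x)
                for con, c in zip(diag.contacts.constraints(), C):
                    ids = ";".join(str(i) for i in con.node_ids)
                    log_fh.write(f"{t:.9g},{con.kind},{ids},{c:.9g}\n")
            for fn in fns:
                after = getattr(fn, "after_step", None)
                if after is not None:
                    after(model)
    finally:
        if traj_fh:
            traj_fh.close()
        if log_fh:
            log_fh.close()
    return ScenarioResult(
        time=np.asarray(times),
        series={n: np.asarray(v) for n, v in samples.items()},
        metadata={"dt": cfg.dt, "iterations": cfg.iterations,
                  "gravity": cfg.gravity.tolist(), "duration": duration,
                  "t0": t0, "mode": model.mode},
    )
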