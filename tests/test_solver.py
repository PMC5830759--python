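"""Timestepping: closed-form limits, PBD equivalence, conservation."""

import numpy as np
import pytest

from softpbd.constraints import ConstraintBatch
from softpbd.errors import SolverError
from softpbd.forces import MaterialParams, ParticleSystem, Springs
from softpbd.model import SimModel
from softpbd.solver import (BoundaryCondition, SolverConfig,
                            predict_positions, prime_state, run, step)

from reference_pbd import classical_pbd_step


def free_model(x, masses, material=None, springs=None, batch=None):
    return SimModel(
        system=ParticleSystem.from_positions(x, masses),
        springs=springs if springs is not None
        else Springs(np.zeros(0, int), np.zeros(0, int), np.zeros(0)),
        batch=batch if batch is not None else ConstraintBatch(),
        material=material if material is not None
        else MaterialParams(k1=0, k2=0, b0=0, b1=0))


class TestPredictor:
    def test_no_force_no_velocity_stays(self, two_node_system):
        x = predict_positions(two_node_system, np.zeros((2, 3)), 0.01)
        assert np.allclose(x, two_node_system.x)

    def test_single_step_gravity(self):
        sys = ParticleSystem.from_positions(np.zeros((1, 3)), np.ones(1))
        g = np.array([0.0, 0.0, -9810.0])
        x = predict_positions(sys, g[None, :], 0.01)
        assert x[0] == pytest.approx(g * 0.01**2)

    def test_fixed_node_never_moves(self):
        sys = ParticleSystem.from_positions(np.zeros((1, 3)), np.zeros(1))
        x = predict_positions(sys, np.full((1, 3), 1e6), 0.01)
        assert np.allclose(x, 0.0)

    def test_nonfinite_force_raises_with_node(self):
        sys = ParticleSystem.from_positions(np.zeros((3, 3)), np.ones(3))
        f = np.zeros((3, 3))
        f[2, 1] = np.nan
        with pytest.raises(SolverError) as err:
            predict_positions(sys, f, 0.01)
        assert err.value.node == 2


class TestClosedForms:
    def test_free_fall_matches_half_g_t_squared(self):
        """100 Verlet steps of free fall land on the ballistic parabola."""
        model = free_model(np.zeros((1, 3)), np.ones(1))
        cfg = SolverConfig(dt=0.001, iterations=1, gravity=(0, 0, -9810.0))
        prime_state(model, cfg)
        run(model, cfg, duration=0.1)
        z = model.system.x[0, 2]
        expected = 0.5 * (-9810.0) * 0.1**2
        assert abs(z - expected) / abs(expected) < 0.01

    def test_uniform_motion_without_forces(self):
        model = free_model(np.zeros((1, 3)), np.ones(1))
        v0 = np.array([3.0, -2.0, 1.0])
        model.system.v = v0[None, :].copy()
        cfg = SolverConfig(dt=0.01, iterations=1)
        prime_state(model, cfg)
        run(model, cfg, duration=1.0)
        assert np.allclose(model.system.x[0], v0 * 1.0, rtol=1e-9)

    def test_two_node_spring_frequency(self):
        """Linear-regime frequency matches sqrt(2 k1/m)/(2 pi) within 5%."""
        k1, m = 10.0, 1.0
        mat = MaterialParams(k1=k1, k2=0.0, b0=0.0, b1=0.0, dl_c=1e6)
        x = np.array([[0.0, 0, 0], [1.02, 0, 0]])
        springs = Springs([0], [1], [1.0])
        model = free_model(x, np.full(2, m), material=mat, springs=springs)
        model.system.x_rest = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        f_ana = np.sqrt(2 * k1 / m) / (2 * np.pi)
        cfg = SolverConfig(dt=1 / (100 * f_ana), iterations=1)
        res = run(model, cfg, duration=6 / f_ana,
                  probes=[("node_position", 1)], probe_names=["p"])
        sep = np.array([p[0] for p in res["p"]])
        sig = sep - sep.mean()
        cross = np.flatnonzero(np.diff(np.sign(sig)) != 0)
        period = 2 * np.mean(np.diff(res.time[cross]))
        assert abs(1 / period - f_ana) / f_ana < 0.05

    def test_energy_dissipates_with_damper(self):
        """Free two-node spring with damping: mechanical energy decays."""
        k1, m = 10.0, 1.0
        mat = MaterialParams(k1=k1, k2=0.0, b0=1.0, b1=0.0, dl_c=1e6)
        x = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        springs = Springs([0], [1], [1.0])
        model = free_model(x, np.full(2, m), material=mat, springs=springs)
        cfg = SolverConfig(dt=0.005, iterations=1)

        def energy():
            s = model.system
            dl = np.linalg.norm(s.x[1] - s.x[0]) - 1.0
            ke = 0.5 * m * (s.v**2).sum()
            return ke + 0.5 * k1 * dl**2

        energies = [energy()]
        for k in range(800):
            step(model, cfg, t=k * cfg.dt)
            energies.append(energy())
        e = np.array(energies)
        assert np.all(np.diff(e) <= 1e-9 * e[0])  # non-increasing
        assert e[-1] < 0.2 * e[0]


class TestPBDLimitEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_one_step_matches_classical_reference(self, seed):
        """Springs/dampers off, alpha=0: the solver is classical PBD."""
        rng = np.random.default_rng(seed)
        n = 10
        x = rng.normal(size=(n, 3)) * 2
        masses = rng.uniform(0.5, 2.0, n)
        masses[0] = 0.0  # one fixed node
        cons = []
        batch = ConstraintBatch()
        for _ in range(12):
            i, j = map(int, rng.choice(n, 2, replace=False))
            rest = float(rng.uniform(0.5, 2.0))
            cons.append((i, j, rest))
            batch.add_distance(i, j, rest, alpha=0.0)

        model = free_model(x, masses, batch=batch)
        forces = rng.normal(size=(n, 3)) * 10
        w = model.system.w.copy()
        x_prev = model.system.x_prev.copy()
        model.bcs.append(BoundaryCondition(
            "applied_force", np.arange(n), value=np.zeros(3)))
        # apply the random per-node forces through the external-force hook
        for node in range(n):
            model.bcs.append(BoundaryCondition("applied_force", [node],
                                               value=forces[node]))
        cfg = SolverConfig(dt=0.01, iterations=5)
        step(model, cfg, t=0.0)
        expected = classical_pbd_step(x, x_prev, w, forces, cons,
                                      dt=0.01, iterations=5)
        assert np.abs(model.system.x - expected).max() < 1e-9


class TestConservationAndDeterminism:
    def test_momentum_drift_free_floating(self):
        """Free-floating springy body: momentum drift < 1e-6 relative."""
        from softpbd.geometry import build_model, generate_cube_lattice

        mesh = generate_cube_lattice(20.0, 2)
        mat = MaterialParams(k1=1.0, k2=10.0, b0=0.0, b1=0.0, alpha=0.0)
        model = build_model(mesh, mat)
        v0 = np.array([5.0, 2.0, -1.0])
        rng = np.random.default_rng(5)
        model.system.v = v0 + rng.normal(scale=2.0,
                                         size=model.system.x.shape)
        cfg = SolverConfig(dt=0.005, iterations=10)
        prime_state(model, cfg)
        m = model.system.masses()
        p0 = (m[:, None] * model.system.v).sum(axis=0)
        run(model, cfg, duration=100 * cfg.dt)
        p1 = (m[:, None] * model.system.v).sum(axis=0)
        assert np.linalg.norm(p1 - p0) / np.linalg.norm(p0) < 1e-6

    def test_run_is_deterministic(self):
        from softpbd.experiments import cube_scenario

        def once():
            mat = MaterialParams(k1=0.25, k2=10.0, b0=2.0, b1=1000.0)
            model, test = cube_scenario(mat, divisions=2)
            model.bcs.append(BoundaryCondition(
                "prescribed_velocity", [test], value=(0.0, 0.0, -10.0)))
            cfg = SolverConfig(dt=0.005, iterations=10)
            return run(model, cfg, duration=0.2,
                       probes=[("displacement", test, (0, 0, -1))],
                       probe_names=["d"])

        a, b = once(), once()
        assert np.array_equal(a["d"], b["d"])
        assert np.array_equal(a.time, b.time)

    def test_zero_duration_gives_empty_series(self):
        model = free_model(np.zeros((1, 3)), np.ones(1))
        cfg = SolverConfig(dt=0.01, iterations=1)
        res = run(model, cfg, duration=0.0, probes=[("kinetic_energy",)])
        assert len(res.time) == 0


class TestBoundaryConditions:
    def test_prescribed_velocity_drives_node(self):
        model = free_model(np.zeros((1, 3)), np.ones(1))
        model.bcs.append(BoundaryCondition("prescribed_velocity", [0],
                                           value=(0, 0, -10.0)))
        cfg = SolverConfig(dt=0.01, iterations=1)
        run(model, cfg, duration=0.5)
        assert model.system.x[0, 2] == pytest.approx(-5.0)

    def test_schedule_window(self):
        model = free_model(np.zeros((1, 3)), np.ones(1))
        model.bcs.append(BoundaryCondition("prescribed_velocity", [0],
                                           value=(1.0, 0, 0),
                                           schedule=(0.0, 0.1)))
        cfg = SolverConfig(dt=0.01, iterations=1)
        run(model, cfg, duration=0.3)
        # moved only during the window, then drifts with its velocity
        assert model.system.x[0, 0] > 0.1

    def test_prescribed_displacement_targets(self):
        model = free_model(np.zeros((2, 3)), np.ones(2))
        targets = np.array([[0.0, 0, -5.0], [0.0, 0, -7.0]])
        model.bcs.append(BoundaryCondition("prescribed_displacement", [0, 1],
                                           targets=targets))
        cfg = SolverConfig(dt=0.01, iterations=1)
        step(model, cfg, 0.0)
        assert np.allclose(model.system.x, targets)


class TestRunExtras:
    def test_substeps_match_finer_timestep(self):
        """max_substeps=4 at dt reproduces a dt/4 run, sampling included."""
        from softpbd.solver import SolverConfig, run
        import numpy as np

        def make():
            m = free_model(np.zeros((1, 3)), np.ones(1))
            m.system.v = np.array([[1.0, 0.0, 0.0]])
            return m

        m1 = make()
        cfg = SolverConfig(dt=0.02, iterations=1, max_substeps=4,
                           gravity=(0, 0, -100.0))
        r1 = run(m1, cfg, duration=0.2, probes=[("node_position", 0)],
                 probe_names=["p"])
        m2 = make()
        fine = SolverConfig(dt=0.005, iterations=1, gravity=(0, 0, -100.0))
        r2 = run(m2, fine, duration=0.2, probes=[("node_position", 0)],
                 probe_names=["p"], sample_every=4)
        assert np.allclose(r1.time, r2.time)
        assert np.allclose(np.array([p for p in r1["p"]]),
                           np.array([p for p in r2["p"]]))

    def test_trajectory_and_contact_log_written(self, tmp_path):
        from softpbd.collision import CollisionSpec
        from softpbd.forces import MaterialParams
        from softpbd.solver import SolverConfig, run
        import numpy as np

        model = free_model(np.array([[0.0, 0, 0], [0.0, 0, 2.2]]),
                           np.array([0.0, 1.0]),
                           material=MaterialParams(k1=0, k2=0, b0=1, b1=0))
        model.collision = CollisionSpec(sphere_nodes=[0, 1],
                                        sphere_radii=1.0,
                                        self_collision=True)
        traj = tmp_path / "trajectory.csv"
        clog = tmp_path / "contacts.csv"
        cfg = SolverConfig(dt=0.005, iterations=5, gravity=(0, 0, -9810.0))
        run(model, cfg, duration=0.1, trajectory=traj, contact_log=clog)
        tlines = traj.read_text().splitlines()
        assert tlines[0] == "t,node,x,y,z"
        assert len(tlines) == 1 + 2 * 20  # two nodes, twenty samples
        llines = clog.read_text().splitlines()
        assert llines[0] == "t,kind,nodes,C"
        assert len(llines) > 1  # the falling sphere hits the fixed one
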