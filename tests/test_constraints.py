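"""Constraint functions, gradients and compliant projection."""

import numpy as np
import pytest

from softpbd.constraints import (Constraint, ConstraintBatch, KIND_CONTACT_VT,
                                 KIND_DISTANCE, KIND_OVERSTRETCH,
                                 KIND_TET_VOLUME, SurfaceVolumeConstraint,
                                 batch_C_grads, eval_distance,
                                 eval_overstretch, eval_surface_volume,
                                 eval_tet_volume, eval_vertex_triangle,
                                 project, project_surface_volume)
from softpbd.forces import ParticleSystem
from softpbd.geometry import generate_icosphere, mesh_volume


def fd_gradient(fn, points, eps=1e-6):
    """Central finite differences of a constraint's C wrt every point."""
    grads = []
    for pi in range(len(points)):
        g = np.zeros(3)
        for d in range(3):
            pp = [p.copy() for p in points]
            pm = [p.copy() for p in points]
            pp[pi][d] += eps
            pm[pi][d] -= eps
            g[d] = (fn(pp)[0] - fn(pm)[0]) / (2 * eps)
        grads.append(g)
    return grads


class TestEvaluations:
    def test_distance_examples(self):
        C, (gp, gq) = eval_distance([0, 0, 0], [3, 0, 0], 2.0)
        assert C == pytest.approx(1.0)
        assert gq == pytest.approx([1, 0, 0])
        assert gp == pytest.approx([-1, 0, 0])
        C, _ = eval_distance([0, 0, 0], [2, 0, 0], 2.0)
        assert C == pytest.approx(0.0)
        C, _ = eval_distance([0, 0, 0], [1.5, 0, 0], 2.0)
        assert C == pytest.approx(-0.5)  # penetration depth

    def test_tet_volume_examples(self):
        tet = [np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2]]
        C, grads = eval_tet_volume(*tet, 1.0 / 6.0)
        assert C == pytest.approx(0.0)
        C, _ = eval_tet_volume(*(2 * p for p in tet), 1.0 / 6.0)
        assert C == pytest.approx(7.0 / 6.0)  # volume scales as L^3
        assert np.allclose(np.sum(grads, axis=0), 0.0, atol=1e-12)

    def test_surface_volume_cube_and_translation(self, rng):
        mesh = generate_icosphere(2.0, 1)
        v0 = mesh_volume(mesh)
        C, g = eval_surface_volume(mesh.vertices, mesh.triangles, v0)
        assert C == pytest.approx(0.0, abs=1e-9)
        shift = rng.normal(size=3) * 5
        C2, _ = eval_surface_volume(mesh.vertices + shift, mesh.triangles, v0)
        assert C2 == pytest.approx(0.0, abs=1e-9 * v0)
        assert np.abs(g.sum(axis=0)).max() < 1e-12 * np.abs(g).max()

    def test_overstretch_activity(self):
        assert eval_overstretch([0, 0, 0], [1, 0, 0], 1.0, 0.5) is None
        C, (g1, g2) = eval_overstretch([2, 0, 0], [0, 0, 0], 1.0, 0.5)
        assert C == pytest.approx(-0.75)
        assert np.allclose(g1, -g2)

    def test_vertex_triangle_examples(self):
        tri = [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        C, grads = eval_vertex_triangle(np.array([0.2, 0.2, 0.5]), *tri, 1.0)
        assert C == pytest.approx(-0.5)
        assert grads[0] == pytest.approx([0, 0, 1])
        C, _ = eval_vertex_triangle(np.array([0.2, 0.2, 2.0]), *tri, 1.0)
        assert C == pytest.approx(1.0)  # separated, unilateral would skip
        # q at height exactly r
        C, _ = eval_vertex_triangle(np.array([0.2, 0.2, 1.0]), *tri, 1.0)
        assert C == pytest.approx(0.0)

    def test_degenerate_cases_warn(self):
        with pytest.warns(RuntimeWarning):
            assert eval_distance([0, 0, 0], [0, 0, 0], 1.0) is None
        with pytest.warns(RuntimeWarning):
            assert eval_vertex_triangle(np.ones(3), np.zeros(3), np.zeros(3),
                                        np.zeros(3), 0.5) is None


class TestGradients:
    """Analytic gradients match central finite differences (all types)."""

    def test_distance(self, rng):
        for _ in range(20):
            p, q = rng.normal(size=(2, 3)) * 2
            C, grads = eval_distance(p, q, 0.7)
            fd = fd_gradient(lambda pts: eval_distance(pts[0], pts[1], 0.7),
                             [p, q])
            for a, b in zip(grads, fd):
                assert np.allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_tet_volume(self, rng):
        for _ in range(20):
            pts = list(rng.normal(size=(4, 3)))
            _, grads = eval_tet_volume(*pts, 0.1)
            fd = fd_gradient(lambda ps: eval_tet_volume(*ps, 0.1), pts)
            for a, b in zip(grads, fd):
                assert np.allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_overstretch(self, rng):
        for _ in range(20):
            p1 = rng.normal(size=3)
            p2 = p1 + rng.normal(size=3) * 4
            res = eval_overstretch(p1, p2, 1.0, 0.3)
            if res is None:
                continue
            _, grads = res
            fd = fd_gradient(lambda ps: eval_overstretch(ps[0], ps[1],
                                                         1.0, 0.3), [p1, p2])
            for a, b in zip(grads, fd):
                assert np.allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_vertex_triangle_exact_mode(self, rng):
        for _ in range(20):
            pts = list(rng.normal(size=(4, 3)))
            res = eval_vertex_triangle(*pts, 0.3,
                                       exact_normal_gradients=True)
            if res is None:
                continue
            _, grads = res
            fd = fd_gradient(
                lambda ps: eval_vertex_triangle(
                    *ps, 0.3, exact_normal_gradients=True), pts)
            for a, b in zip(grads, fd):
                assert np.allclose(a, b, rtol=1e-5, atol=1e-6)

    def test_surface_volume(self, rng):
        mesh = generate_icosphere(1.0, 0)
        x = mesh.vertices + rng.normal(size=mesh.vertices.shape) * 0.1
        _, g = eval_surface_volume(x, mesh.triangles, 1.0)
        eps = 1e-6
        for i in range(0, len(x), 3):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += eps
                xm[i, d] -= eps
                num = (eval_surface_volume(xp, mesh.triangles, 1.0)[0]
                       - eval_surface_volume(xm, mesh.triangles, 1.0)[0]) \
                    / (2 * eps)
                assert num == pytest.approx(g[i, d], rel=1e-5, abs=1e-7)


class TestProjection:
    def test_classical_distance_projection(self):
        """alpha=0 distance projection reduces to classical PBD in one step."""
        sys = ParticleSystem.from_positions(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.ones(2))
        con = Constraint(kind=KIND_DISTANCE, node_ids=(0, 1), rest=1.0)
        dlam = project(con, sys, dt=0.01)
        assert dlam == pytest.approx(-0.5)
        assert sys.x[0] == pytest.approx([0.5, 0, 0])
        assert sys.x[1] == pytest.approx([1.5, 0, 0])

    def test_fixed_node_takes_no_correction(self):
        sys = ParticleSystem.from_positions(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.array([0.0, 1.0]))
        con = Constraint(kind=KIND_DISTANCE, node_ids=(0, 1), rest=1.0)
        project(con, sys, dt=0.01)
        assert sys.x[0] == pytest.approx([0, 0, 0])
        assert sys.x[1] == pytest.approx([1.0, 0, 0])  # full correction

    def test_infinite_compliance_freezes_positions(self):
        sys = ParticleSystem.from_positions(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.ones(2))
        con = Constraint(kind=KIND_DISTANCE, node_ids=(0, 1), rest=1.0,
                         alpha=1e12)
        dlam = project(con, sys, dt=0.01)
        assert abs(dlam) < 1e-9
        assert sys.x[1] == pytest.approx([2.0, 0, 0], abs=1e-9)

    def test_all_fixed_zero_compliance_skips_with_warning(self):
        sys = ParticleSystem.from_positions(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.zeros(2))
        con = Constraint(kind=KIND_DISTANCE, node_ids=(0, 1), rest=1.0)
        with pytest.warns(RuntimeWarning):
            project(con, sys, dt=0.01)

    def test_overstretch_clamps_to_band_edge(self):
        """Repeated projection pulls |p1-p2| back to (1+k_ratio)*l0."""
        sys = ParticleSystem.from_positions(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.ones(2))
        con = Constraint(kind=KIND_OVERSTRETCH, node_ids=(0, 1), rest=1.0,
                         aux=0.5, unilateral=True)
        for _ in range(50):
            project(con, sys, dt=0.01)
        assert np.linalg.norm(sys.x[1] - sys.x[0]) == pytest.approx(
            1.5, abs=1e-6)

    def test_projection_conserves_momentum(self, rng):
        """Bilateral constraints on free nodes: mass-weighted dx sums to 0."""
        for kind, nn in ((KIND_DISTANCE, 2), (KIND_TET_VOLUME, 4)):
            masses = rng.uniform(0.5, 3.0, nn)
            x = rng.normal(size=(nn, 3))
            sys = ParticleSystem.from_positions(x, masses)
            con = Constraint(kind=kind, node_ids=tuple(range(nn)), rest=0.3)
            before = (masses[:, None] * sys.x).sum(axis=0)
            project(con, sys, dt=0.01)
            after = (masses[:, None] * sys.x).sum(axis=0)
            assert np.allclose(before, after, atol=1e-9)

    def test_xpbd_converged_constraint_satisfies_compliance_relation(self):
        """Converged C equals -alpha_tilde * lambda, iteration independent."""
        def converge(iterations):
            sys = ParticleSystem.from_positions(
                np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.ones(2))
            con = Constraint(kind=KIND_DISTANCE, node_ids=(0, 1), rest=1.0,
                             alpha=2e-4)
            dt = 0.01
            for _ in range(iterations):
                project(con, sys, dt)
            C = np.linalg.norm(sys.x[1] - sys.x[0]) - 1.0
            return C, con.lam, con.alpha / dt**2

        C5, lam5, at = converge(5)
        C50, lam50, _ = converge(50)
        assert C50 == pytest.approx(-at * lam50, rel=1e-6)
        assert C5 == pytest.approx(C50, abs=1e-4)

    def test_surface_volume_projection_restores_volume(self):
        mesh = generate_icosphere(1.0, 1)
        v0 = mesh_volume(mesh)
        x = mesh.vertices * 1.1  # inflated by 33% in volume
        w = np.ones(len(x))
        con = SurfaceVolumeConstraint(triangles=mesh.triangles, rest=v0)
        for _ in range(10):
            project_surface_volume(con, x, w, dt=0.01)
        C, _ = con.evaluate(x)
        assert abs(C) < 1e-8 * v0


class TestBatch:
    def test_batch_matches_reference_projection(self, rng):
        """The compiled sweep equals per-constraint reference projection."""
        from softpbd._kernels import gauss_seidel_sweep

        n = 12
        x = rng.normal(size=(n, 3)) * 2
        w = rng.uniform(0.2, 2.0, n)
        w[rng.choice(n, 2, replace=False)] = 0.0
        sys_k = ParticleSystem.from_positions(x, np.ones(n))
        sys_k.w = w.copy()
        sys_r = ParticleSystem.from_positions(x, np.ones(n))
        sys_r.w = w.copy()

        batch = ConstraintBatch()
        cons = []
        for _ in range(10):
            i, j = map(int, rng.choice(n, 2, replace=False))
            rest = float(rng.uniform(0.5, 2))
            alpha = float(rng.uniform(0, 0.01))
            batch.add_distance(i, j, rest, alpha=alpha)
            cons.append(Constraint(KIND_DISTANCE, (i, j), rest, alpha=alpha))
        for _ in range(5):
            ids = tuple(map(int, rng.choice(n, 4, replace=False)))
            v0 = float(rng.uniform(0.05, 0.3))
            batch.add_tet_volume(*ids, v0, alpha=1e-3)
            cons.append(Constraint(KIND_TET_VOLUME, ids, v0, alpha=1e-3))
            i, j = map(int, rng.choice(n, 2, replace=False))
            batch.add_overstretch(i, j, 1.0, 0.4)
            cons.append(Constraint(KIND_OVERSTRETCH, (i, j), 1.0, aux=0.4,
                                   unilateral=True))
            ids = tuple(map(int, rng.choice(n, 4, replace=False)))
            batch.add_contact_vt(*ids, 0.3)
            cons.append(Constraint(KIND_CONTACT_VT, ids, 0.3,
                                   unilateral=True))

        dt = 0.01
        a = batch.arrays()
        for _ in range(4):
            gauss_seidel_sweep(sys_k.x, sys_k.w, a["kind"], a["nodes"],
                               a["rest"], a["aux"], a["alpha"] / dt**2,
                               a["lam"], a["unilateral"])
            for c in cons:
                project(c, sys_r, dt)
        assert np.abs(sys_k.x - sys_r.x).max() < 1e-12
        assert np.abs(a["lam"] - [c.lam for c in cons]).max() < 1e-12

    def test_vectorized_eval_matches_scalar(self, rng):
        batch = ConstraintBatch()
        n = 8
        x = rng.normal(size=(n, 3))
        batch.add_distance(0, 1, 1.0)
        batch.add_tet_volume(0, 1, 2, 3, 0.1)
        batch.add_overstretch(4, 5, 0.5, 0.2)
        batch.add_contact_vt(6, 0, 1, 2, 0.3)
        C, G, active = batch_C_grads(x, batch.arrays())
        for c, con in enumerate(batch.constraints()):
            res = con.evaluate(x)
            if res is None or (con.unilateral and res[0] >= 0):
                continue
            assert active[c]
            assert C[c] == pytest.approx(res[0])
            for slot, g in enumerate(res[1]):
                assert np.allclose(G[c, slot], g)

    def test_debug_dump_lists_every_constraint(self):
        batch = ConstraintBatch()
        batch.add_distance(0, 1, 1.0)
        batch.add_overstretch(1, 2, 2.0, 1.0)
        dump = batch.debug_dump().splitlines()
        assert len(dump) == 2
        assert dump[0].startswith("distance nodes=[0, 1]")
        assert dump[1].startswith("overstretch nodes=[1, 2]")
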