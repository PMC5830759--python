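"""Constraint functions, gradients and compliant (XPBD) projection.

Each constraint is a scalar function C(x) of a few node positions.  The
compliant projection update used throughout the package is

    dlam = -(C + at*lam) / (sum_k w_k |grad_k C|^2 + at),      at = alpha/dt^2
    lam += dlam;   x_k += w_k * grad_k C * dlam

which reduces to classical PBD projection when alpha = 0 and decouples the
converged stiffness from iteration count and timestep when alpha > 0.
The accumulated multiplier ``lam`` is reset at the start of every timestep.

Constraint kinds:

* ``distance`` — |q - p| - rest (also used, unilaterally, for
  sphere-sphere contacts);
* ``tet_volume`` — signed tetrahedron volume minus rest volume (local
  incompressibility of solid organs);
* ``surface_volume`` — enclosed volume of a closed triangle surface minus
  rest volume (global incompressibility of hollow organs), including the
  1/6 divergence-theorem normalization so the reference value is a true
  geometric volume;
* ``overstretch`` — unilateral band limiter (kratio*l0)^2 - (|p1-p2|-l0)^2
  that clamps spring elongation *and* compression back to
  |dl| <= kratio*l0, suppressing local superelasticity near load points;
* ``contact_vertex_triangle`` — signed plane distance minus sphere radius
  (unilateral).

Sign conventions follow the canonical XPBD update (the negative sign on
``dlam``); positive-sign updates diverge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "KIND_DISTANCE", "KIND_TET_VOLUME", "KIND_OVERSTRETCH",
    "KIND_CONTACT_SS", "KIND_CONTACT_VT", "KIND_SURFACE_VOLUME",
    "Constraint", "ConstraintBatch", "SurfaceVolumeConstraint",
    "eval_distance", "eval_tet_volume", "eval_surface_volume",
    "eval_overstretch", "eval_vertex_triangle",
    "project", "project_surface_volume",
]

KIND_DISTANCE = 0
KIND_TET_VOLUME = 1
KIND_OVERSTRETCH = 2
KIND_CONTACT_SS = 3
KIND_CONTACT_VT = 4
KIND_SURFACE_VOLUME = 5

_KIND_NAMES = {
    KIND_DISTANCE: "distance",
    KIND_TET_VOLUME: "tet_volume",
    KIND_OVERSTRETCH: "overstretch",
    KIND_CONTACT_SS: "contact_sphere_sphere",
    KIND_CONTACT_VT: "contact_vertex_triangle",
    KIND_SURFACE_VOLUME: "surface_volume",
}

_EPS = 1e-9


# ---------------------------------------------------------------------------
# scalar constraint evaluations (reference path; the solver's hot loop lives
# in softpbd._kernels and is cross-checked against these in the test suite)
# ---------------------------------------------------------------------------

def eval_distance(p, q, rest):
    """C = |q - p| - rest; gradient wrt q is the unit vector from p to q.

    Returns ``(C, (grad_p, grad_q))`` or ``None`` for a degenerate pair.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    length = float(np.linalg.norm(d))
    if length < _EPS:
        warnings.warn("degenerate distance constraint skipped", RuntimeWarning,
                      stacklevel=2)
        return None
    n = d / length
    return length - rest, (-n, n)


def eval_tet_volume(p1, p2, p3, p4, V0):
    """Signed tet volume minus V0 and its analytic position gradients.

    The four gradients sum to zero (the volume is translation invariant).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    u, v, w = p2 - p1, p3 - p1, p4 - p1
    C = float(np.cross(u, v) @ w) / 6.0 - V0
    g2 = np.cross(v, w) / 6.0
    g3 = np.cross(w, u) / 6.0
    g4 = np.cross(u, v) / 6.0
    g1 = -(g2 + g3 + g4)
    return C, (g1, g2, g3, g4)


def eval_surface_volume(vertices, triangles, V0):
    """Enclosed volume of a closed oriented surface minus V0, with gradients.

    ``C = (1/6) sum_t (p_t1 x p_t2) . p_t3 - V0``; the per-node gradient
    accumulates the cross-product terms of every incident triangle and all
    gradients sum to zero.
    """
    x = np.asarray(vertices, float)
    t = np.asarray(triangles, int)
    a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    C = float(np.einsum("ij,ij->i", np.cross(a, b), c).sum()) / 6.0 - V0
    g = np.zeros_like(x)
    np.add.at(g, t[:, 0], np.cross(b, c) / 6.0)
    np.add.at(g, t[:, 1], np.cross(c, a) / 6.0)
    np.add.at(g, t[:, 2], np.cross(a, b) / 6.0)
    return C, g


def eval_overstretch(p1, p2, l0, k_ratio):
    """Band limiter C = (k_ratio*l0)^2 - (|p1-p2| - l0)^2.

    Returns ``None`` while the elongation is inside the band (inactive) or
    the pair is degenerate; when active, C < 0 and projecting with
    alpha = 0 clamps the elongation back to ``|dl| = k_ratio * l0``.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = p1 - p2
    length = float(np.linalg.norm(d))
    if length < _EPS:
        warnings.warn("degenerate overstretch pair skipped", RuntimeWarning,
                      stacklevel=2)
        return None
    dl = length - l0
    band = k_ratio * l0
    if dl * dl <= band * band:
        return None
    C = band * band - dl * dl
    g1 = (-2.0 * dl / length) * d
    return C, (g1, -g1)


def eval_vertex_triangle(q, p1, p2, p3, r, exact_normal_gradients=False):
    """Signed plane distance of q to triangle (p1, p2, p3) minus r.

    ``C = (q - p1) . n - r`` with n the unit normal of the triangle.  By
    default the triangle-node gradients treat n as locally constant and
    distribute ``-n`` with the barycentric weights of q's in-plane
    projection (standard PBD contact practice, exactly momentum
    conserving).  ``exact_normal_gradients=True`` differentiates the unit
    normal as well, giving gradients that match finite differences of C.
    Returns ``None`` for a degenerate triangle.
    """
    q, p1, p2, p3 = (np.asarray(p, float) for p in (q, p1, p2, p3))
    e1, e2 = p2 - p1, p3 - p1
    n = np.cross(e1, e2)
    nn = float(np.linalg.norm(n))
    if nn < 1e-12:
        warnings.warn("degenerate triangle in vertex-triangle constraint",
                      RuntimeWarning, stacklevel=2)
        return None
    nhat = n / nn
    d = q - p1
    C = float(d @ nhat) - r
    gq = nhat
    if exact_normal_gradients:
        dt_ = d - (d @ nhat) * nhat
        g2 = np.cross(e2, dt_) / nn
        g3 = -np.cross(e1, dt_) / nn
        g1 = -nhat - np.cross(e2 - e1, dt_) / nn
    else:
        b2, b3 = _barycentric_2d(e1, e2, d - (d @ nhat) * nhat)
        b1 = 1.0 - b2 - b3
        g1, g2, g3 = -b1 * nhat, -b2 * nhat, -b3 * nhat
    return C, (gq, g1, g2, g3)


def _barycentric_2d(e1, e2, dt_):
    """Barycentric weights (wrt p2, p3) of an in-plane vector from p1."""
    a11 = e1 @ e1
    a12 = e1 @ e2
    a22 = e2 @ e2
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-18:
        return 0.0, 0.0
    r1, r2 = e1 @ dt_, e2 @ dt_
    return (a22 * r1 - a12 * r2) / det, (a11 * r2 - a12 * r1) / det


# ---------------------------------------------------------------------------
# constraint containers
# ---------------------------------------------------------------------------

@dataclass
class Constraint:
    """A single constraint record (reference/object form).

    ``rest`` is the scalar reference (rest length, rest volume or radius
    sum); ``aux`` carries the overstretch band half-width ``k_ratio*l0``
    where applicable.  ``lam`` is the multiplier accumulated within the
    current timestep.
    """

    kind: int
    node_ids: tuple
    rest: float
    alpha: float = 0.0
    lam: float = 0.0
    aux: float = 0.0
    unilateral: bool = False

    def __post_init__(self):
        if self.alpha < 0:
            raise InvalidArgumentError("compliance alpha must be >= 0")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise InvalidArgumentError("constraint node ids must be distinct")

    def evaluate(self, x, exact_normal_gradients=False):
        """(C, per-node gradients) at positions ``x``, or None if inactive."""
        ids = self.node_ids
        if self.kind in (KIND_DISTANCE, KIND_CONTACT_SS):
            return eval_distance(x[ids[0]], x[ids[1]], self.rest)
        if self.kind == KIND_TET_VOLUME:
            return eval_tet_volume(*(x[i] for i in ids), self.rest)
        if self.kind == KIND_OVERSTRETCH:
            return eval_overstretch(x[ids[0]], x[ids[1]], self.rest,
                                    self.aux / self.rest)
        if self.kind == KIND_CONTACT_VT:
            return eval_vertex_triangle(
                *(x[i] for i in ids), self.rest,
                exact_normal_gradients=exact_normal_gradients)
        raise InvalidArgumentError(f"cannot evaluate kind {self.kind}")


def project(constraint: Constraint, system, dt: float):
    """Apply one compliant projection of ``constraint`` to ``system``.

    Updates positions in place and the constraint's multiplier; returns the
    multiplier increment (0.0 when the constraint is inactive or skipped).
    Unilateral constraints project only when C < 0.  Fixed nodes (w = 0)
    never move; if every involved node is fixed and the compliance is zero
    the projection is skipped with a warning.
    """
    res = constraint.evaluate(system.x)
    if res is None:
        return 0.0
    C, grads = res
    if constraint.unilateral and C >= 0.0:
        return 0.0
    at = constraint.alpha / (dt * dt)
    w = system.w
    denom = at + sum(w[i] * float(g @ g)
                     for i, g in zip(constraint.node_ids, grads))
    if denom <= 0.0:
        warnings.warn("constraint with all nodes fixed and zero compliance "
                      "skipped", RuntimeWarning, stacklevel=2)
        return 0.0
    dlam = -(C + at * constraint.lam) / denom
    constraint.lam += dlam
    for i, g in zip(constraint.node_ids, grads):
        system.x[i] += w[i] * dlam * g
    return dlam


@dataclass
class SurfaceVolumeConstraint:
    """Single global enclosed-volume constraint over a closed surface."""

    triangles: np.ndarray
    rest: float
    alpha: float = 0.0
    lam: float = 0.0

    def evaluate(self, x):
        return eval_surface_volume(x, self.triangles, self.rest)


def project_surface_volume(con: SurfaceVolumeConstraint, x, w, dt: float):
    """Compliant projection of the global volume constraint (vectorized)."""
    C, g = con.evaluate(x)
    at = con.alpha / (dt * dt)
    denom = at + float((w[:, None] * g * g).sum())
    if denom <= 0.0:
        return 0.0
    dlam = -(C + at * con.lam) / denom
    con.lam += dlam
    x += (w * dlam)[:, None] * g
    return dlam


class ConstraintBatch:
    """Struct-of-arrays batch of kernel-projectable constraints.

    Constraints are processed in insertion order by the Gauss-Seidel sweep
    (``softpbd._kernels.gauss_seidel_sweep``).  ``nodes`` is padded with -1
    for two-node constraints.
    """

    def __init__(self):
        self._kind, self._nodes, self._rest = [], [], []
        self._aux, self._alpha, self._uni = [], [], []
        self._arrays = None

    def __len__(self):
        return len(self._kind)

    def _add(self, kind, nodes, rest, aux, alpha, unilateral):
        if alpha < 0:
            raise InvalidArgumentError("compliance alpha must be >= 0")
        self._kind.append(kind)
        self._nodes.append(tuple(nodes) + (-1,) * (4 - len(nodes)))
        self._rest.append(float(rest))
        self._aux.append(float(aux))
        self._alpha.append(float(alpha))
        self._uni.append(bool(unilateral))
        self._arrays = None

    def add_distance(self, i, j, rest, alpha=0.0, unilateral=False):
        self._add(KIND_DISTANCE, (i, j), rest, 0.0, alpha, unilateral)

    def add_tet_volume(self, i, j, k, l, V0, alpha=0.0):
        self._add(KIND_TET_VOLUME, (i, j, k, l), V0, 0.0, alpha, False)

    def add_overstretch(self, i, j, l0, band, alpha=0.0):
        self._add(KIND_OVERSTRETCH, (i, j), l0, band, alpha, True)

    def add_contact_ss(self, i, j, radius_sum):
        self._add(KIND_CONTACT_SS, (i, j), radius_sum, 0.0, 0.0, True)

    def add_contact_vt(self, q, p1, p2, p3, radius):
        self._add(KIND_CONTACT_VT, (q, p1, p2, p3), radius, 0.0, 0.0, True)

    def arrays(self):
        """Compiled (kind, nodes, rest, aux, alpha, lam, unilateral) arrays."""
        if self._arrays is None:
            self._arrays = dict(
                kind=np.asarray(self._kind, dtype=np.int64),
                nodes=np.asarray(self._nodes, dtype=np.int64).reshape(-1, 4),
                rest=np.asarray(self._rest, dtype=np.float64),
                aux=np.asarray(self._aux, dtype=np.float64),
                alpha=np.asarray(self._alpha, dtype=np.float64),
                lam=np.zeros(len(self._kind), dtype=np.float64),
                unilateral=np.asarray(self._uni, dtype=np.bool_),
            )
        return self._arrays

    def reset_lambdas(self):
        self.arrays()["lam"][:] = 0.0

    def without_kinds(self, kinds) -> "ConstraintBatch":
        """A new batch with every constraint of the given kinds removed."""
        kinds = set(kinds)
        out = ConstraintBatch()
        for c in range(len(self)):
            if self._kind[c] in kinds:
                continue
            nodes = tuple(i for i in self._nodes[c] if i >= 0)
            out._add(self._kind[c], nodes, self._rest[c], self._aux[c],
                     self._alpha[c], self._uni[c])
        return out

    def constraints(self):
        """View the batch as a list of :class:`Constraint` records."""
        a = self.arrays()
        out = []
        for c in range(len(self)):
            ids = tuple(int(i) for i in a["nodes"][c] if i >= 0)
            out.append(Constraint(kind=int(a["kind"][c]), node_ids=ids,
                                  rest=float(a["rest"][c]),
                                  alpha=float(a["alpha"][c]),
                                  lam=float(a["lam"][c]),
                                  aux=float(a["aux"][c]),
                                  unilateral=bool(a["unilateral"][c])))
        return out

    def debug_dump(self) -> str:
        """Plain-text dump, one constraint per line (for test snapshots)."""
        a = self.arrays()
        lines = []
        for c in range(len(self)):
            ids = [int(i) for i in a["nodes"][c] if i >= 0]
            lines.append(
                f"{_KIND_NAMES[int(a['kind'][c])]} nodes={ids} "
                f"rest={a['rest'][c]:.9g} alpha={a['alpha'][c]:.9g} "
                f"lam={a['lam'][c]:.9g}")
        return "\n".join(lines)

    # -- vectorized evaluation (diagnostics, reaction-force probes) --------

    def eval_all(self, x):
        """C values of every constraint (inactive unilaterals report 0)."""
        C, _, active = batch_C_grads(np.asarray(x, float), self.arrays())
        return np.where(active, C, 0.0)

    def constraint_forces(self, x, dt):
        """Per-node force equivalent of accumulated multipliers.

        ``f_k = sum_c lam_c * grad_k C_c / dt^2`` evaluated at positions
        ``x`` — the XPBD force interpretation of the position corrections.
        """
        x = np.asarray(x, float)
        a = self.arrays()
        _, G, active = batch_C_grads(x, a)
        scale = np.where(active, a["lam"], 0.0) / (dt * dt)
        f = np.zeros_like(x)
        nodes = a["nodes"]
        for slot in range(4):
            valid = nodes[:, slot] >= 0
            np.add.at(f, nodes[valid, slot],
                      scale[valid, None] * G[valid, slot])
        return f

    def constraint_forces_at(self, x, dt, only_node: int):
        """Multiplier force on one node (cheap path for force probes)."""
        x = np.asarray(x, float)
        a = self.arrays()
        touch = np.flatnonzero((a["nodes"] == only_node).any(axis=1)
                               & (a["lam"] != 0.0))
        f = np.zeros(3)
        if len(touch) == 0:
            return f
        _, G, active = batch_C_grads(x, a, idx=touch)
        scale = np.where(active, a["lam"][touch], 0.0) / (dt * dt)
        hits = a["nodes"][touch]
        for slot in range(4):
            sel = hits[:, slot] == only_node
            if sel.any():
                f += (scale[sel, None] * G[sel, slot]).sum(axis=0)
        return f


def batch_C_grads(x, arrays, idx=None):
    """Vectorized constraint values and gradients for a batch.

    Returns ``(C, G, active)`` with ``G`` of shape (k, 4, 3) padded with
    zeros for absent nodes.  ``active`` is False for degenerate geometry
    and for unilateral constraints whose C >= 0; their C/G entries are not
    meaningful.  Used for diagnostics and multiplier-force reconstruction;
    the projection itself runs in :mod:`softpbd._kernels`.
    """
    a = arrays
    if idx is None:
        idx = np.arange(len(a["kind"]))
    kind = a["kind"][idx]
    nodes = a["nodes"][idx]
    rest = a["rest"][idx]
    aux = a["aux"][idx]
    uni = a["unilateral"][idx]
    k = len(idx)
    C = np.zeros(k)
    G = np.zeros((k, 4, 3))
    active = np.ones(k, dtype=bool)

    m = (kind == KIND_DISTANCE) | (kind == KIND_CONTACT_SS)
    if m.any():
        i, j = nodes[m, 0], nodes[m, 1]
        d = x[j] - x[i]
        L = np.linalg.norm(d, axis=1)
        ok = L >= _EPS
        n = d / np.where(ok, L, 1.0)[:, None]
        Cm = L - rest[m]
        act = ok & (~uni[m] | (Cm < 0.0))
        C[m] = Cm
        Gm = np.zeros((int(m.sum()), 4, 3))
        Gm[:, 0] = -n
        Gm[:, 1] = n
        G[m] = Gm
        active[m] = act

    m = kind == KIND_TET_VOLUME
    if m.any():
        p = x[nodes[m]]
        u, v, t = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        g2 = np.cross(v, t) / 6.0
        g3 = np.cross(t, u) / 6.0
        g4 = np.cross(u, v) / 6.0
        C[m] = np.einsum("ij,ij->i", g4, t) - rest[m]
        Gm = np.stack([-(g2 + g3 + g4), g2, g3, g4], axis=1)
        G[m] = Gm

    m = kind == KIND_OVERSTRETCH
    if m.any():
        i, j = nodes[m, 0], nodes[m, 1]
        d = x[i] - x[j]
        L = np.linalg.norm(d, axis=1)
        ok = L >= _EPS
        dl = L - rest[m]
        band = aux[m]
        act = ok & (dl * dl > band * band)
        C[m] = band * band - dl * dl
        g1 = (-2.0 * dl / np.where(ok, L, 1.0))[:, None] * d
        Gm = np.zeros((int(m.sum()), 4, 3))
        Gm[:, 0] = g1
        Gm[:, 1] = -g1
        G[m] = Gm
        active[m] = act

    m = kind == KIND_CONTACT_VT
    if m.any():
        q = x[nodes[m, 0]]
        p1, p2, p3 = x[nodes[m, 1]], x[nodes[m, 2]], x[nodes[m, 3]]
        e1, e2 = p2 - p1, p3 - p1
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n, axis=1)
        ok = nn >= 1e-12
        nhat = n / np.where(ok, nn, 1.0)[:, None]
        d = q - p1
        h = np.einsum("ij,ij->i", d, nhat)
        Cm = h - rest[m]
        act = ok & (~uni[m] | (Cm < 0.0))
        dt_ = d - h[:, None] * nhat
        a11 = np.einsum("ij,ij->i", e1, e1)
        a12 = np.einsum("ij,ij->i", e1, e2)
        a22 = np.einsum("ij,ij->i", e2, e2)
        det = a11 * a22 - a12 * a12
        okd = np.abs(det) >= 1e-18
        det = np.where(okd, det, 1.0)
        r1 = np.einsum("ij,ij->i", e1, dt_)
        r2 = np.einsum("ij,ij->i", e2, dt_)
        b2 = (a22 * r1 - a12 * r2) / det
        b3 = (a11 * r2 - a12 * r1) / det
        b1 = 1.0 - b2 - b3
        C[m] = Cm
        Gm = np.zeros((int(m.sum()), 4, 3))
        Gm[:, 0] = nhat
        Gm[:, 1] = -b1[:, None] * nhat
        Gm[:, 2] = -b2[:, None] * nhat
        Gm[:, 3] = -b3[:, None] * nhat
        G[m] = Gm
        active[m] = act & okd
    return C, G, active
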