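"""Nonlinear spring and viscoelastic damper forces.

The elastic backbone of the model is a network of point masses joined by
nonlinear springs.  Each spring responds cubically at small elongation and
linearly beyond a crossover elongation ``dl_c`` (the two branches join with
continuous value and slope).  Viscoelasticity is modelled by a per-node
damper whose coefficient grows linearly with the node's distance from its
rest position:

    f_damper,i = -(b0 + b1 * ||x_i - x_i0||) * v_i

so a strongly displaced region is more strongly damped — this is what
produces creep and stress relaxation at the system level.

Units: positions mm, time s, mass g; forces are therefore in uN
(1 uN = 1 g.mm/s^2) and gravity is 9810 mm/s^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "MaterialParams",
    "Spring",
    "Springs",
    "ParticleSystem",
    "spring_scalar",
    "spring_forces",
    "damper_forces",
]

#: Below this inter-node distance (mm) a spring/constraint pair is treated as
#: degenerate and skipped.
DEGENERATE_EPS = 1e-9


@dataclass
class MaterialParams:
    """Material parameters of the spring/damper/constraint model.

    Parameters
    ----------
    k1 : nonlinear spring stiffness (linear term), uN/mm.
    k2 : cubic spring stiffness coefficient, uN/mm^3.
    dl_c : crossover elongation (mm) between the cubic and linear spring
        branches.  ``None`` (default) means "fractional": each spring uses
        ``dl_c_fraction * l0`` so the cubic regime scales with spring size
        on heterogeneous meshes.
    dl_c_fraction : fraction of the rest length used when ``dl_c is None``.
    b0 : baseline velocity damping, uN.s/mm.
    b1 : viscoelastic damping coefficient, uN.s/mm^2 (multiplies the node's
        displacement from rest).
    k_ratio : overstretch band half-width as a fraction of rest length; a
        spring's elongation is clamped to ``|dl| <= k_ratio * l0`` by a
        hard unilateral constraint.
    alpha : constraint compliance (inverse stiffness); 0 means hard
        constraints, larger values soften them independently of timestep
        and iteration count.
    """

    k1: float = 0.25
    k2: float = 10.0
    dl_c: float | None = None
    dl_c_fraction: float = 0.1
    b0: float = 2.0
    b1: float = 1000.0
    k_ratio: float = 0.5
    alpha: float = 0.0

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidArgumentError("spring stiffnesses k1, k2 must be >= 0")
        if self.dl_c is not None and self.dl_c <= 0:
            raise InvalidArgumentError("dl_c must be positive")
        if self.dl_c is None and self.dl_c_fraction <= 0:
            raise InvalidArgumentError("dl_c_fraction must be positive")
        if self.b0 < 0 or self.b1 < 0:
            raise InvalidArgumentError("damping coefficients must be >= 0")
        if self.k_ratio <= 0:
            raise InvalidArgumentError("k_ratio must be positive")
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be >= 0")

    def crossover(self, l0):
        """Crossover elongation dl_c for springs of rest length ``l0``."""
        if self.dl_c is not None:
            return np.broadcast_to(np.float64(self.dl_c), np.shape(l0)).copy() \
                if np.ndim(l0) else float(self.dl_c)
        out = self.dl_c_fraction * np.asarray(l0, dtype=float)
        return out if np.ndim(l0) else float(out)

    def with_(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Spring:
    """A single spring: node pair with rest length."""

    i: int
    j: int
    l0: float

    def __post_init__(self):
        if self.i == self.j:
            raise InvalidArgumentError("spring endpoints must differ")
        if self.l0 <= 0:
            raise InvalidArgumentError("spring rest length must be positive")


class Springs:
    """Struct-of-arrays spring set: ``i``, ``j`` (int indices), ``l0`` (mm)."""

    def __init__(self, i, j, l0):
        self.i = np.asarray(i, dtype=np.int64)
        self.j = np.asarray(j, dtype=np.int64)
        self.l0 = np.asarray(l0, dtype=np.float64)
        if not (self.i.shape == self.j.shape == self.l0.shape):
            raise InvalidArgumentError("spring arrays must share a shape")
        if np.any(self.i == self.j):
            raise InvalidArgumentError("spring endpoints must differ")
        if np.any(self.l0 <= 0):
            raise InvalidArgumentError("spring rest lengths must be positive")

    def __len__(self):
        return self.i.shape[0]

    def __iter__(self):
        for a, b, l in zip(self.i, self.j, self.l0):
            yield Spring(int(a), int(b), float(l))


@dataclass
class ParticleSystem:
    """Per-node state of the simulation.

    ``x``/``x_prev`` are current and previous positions (n, 3), ``v`` the
    finite-difference velocities, ``w`` inverse masses (0 marks a fixed or
    kinematically driven node) and ``x_rest`` the rest positions used by the
    viscoelastic damper.
    """

    x: np.ndarray
    x_prev: np.ndarray
    v: np.ndarray
    w: np.ndarray
    x_rest: np.ndarray

    def __post_init__(self):
        self.x = np.ascontiguousarray(self.x, dtype=np.float64)
        self.x_prev = np.ascontiguousarray(self.x_prev, dtype=np.float64)
        self.v = np.ascontiguousarray(self.v, dtype=np.float64)
        self.w = np.ascontiguousarray(self.w, dtype=np.float64)
        self.x_rest = np.ascontiguousarray(self.x_rest, dtype=np.float64)
        n = self.x.shape[0]
        for arr, name in ((self.x_prev, "x_prev"), (self.v, "v"), (self.x_rest, "x_rest")):
            if arr.shape != (n, 3):
                raise InvalidArgumentError(f"{name} must have shape ({n}, 3)")
        if self.w.shape != (n,):
            raise InvalidArgumentError(f"w must have shape ({n},)")
        if np.any(self.w < 0):
            raise InvalidArgumentError("inverse masses must be >= 0")
        if not (np.isfinite(self.x).all() and np.isfinite(self.w).all()):
            raise InvalidArgumentError("non-finite entries in particle state")

    @classmethod
    def from_positions(cls, x, masses) -> "ParticleSystem":
        """Build a system at rest from positions and per-node masses (g).

        A non-positive mass marks the node as fixed (infinite mass, w = 0).
        """
        x = np.ascontiguousarray(x, dtype=np.float64)
        masses = np.asarray(masses, dtype=np.float64)
        if masses.ndim == 0:
            masses = np.full(x.shape[0], float(masses))
        w = np.zeros_like(masses)
        np.divide(1.0, masses, out=w, where=masses > 0)
        return cls(x=x.copy(), x_prev=x.copy(), v=np.zeros_like(x), w=w,
                   x_rest=x.copy())

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def masses(self) -> np.ndarray:
        """Node masses; fixed nodes (w = 0) get mass 0 by convention."""
        m = np.zeros_like(self.w)
        np.divide(1.0, self.w, out=m, where=self.w > 0)
        return m


def spring_scalar(dl, params: MaterialParams, dl_c=None):
    """Scalar spring force magnitude for elongation ``dl`` (odd in dl).

    Cubic branch ``k1*dl + k2*dl**3`` for ``|dl| <= dl_c``; linear branch
    ``(A + B*(|dl| - dl_c)) * sign(dl)`` beyond, with ``A = k1*dl_c +
    k2*dl_c**3`` and ``B = k1 + 3*k2*dl_c**2`` so value and slope are
    continuous at the crossover.

    ``dl_c`` overrides the material's crossover (scalar or per-element
    array); by default springs of unit rest length are assumed when the
    material uses a fractional crossover.
    """
    dl = np.asarray(dl, dtype=np.float64)
    if dl_c is None:
        dl_c = params.crossover(1.0)
    dl_c = np.asarray(dl_c, dtype=np.float64)
    a = np.abs(dl)
    # dl*dl*dl (not dl**3): exactly odd in dl and identical rounding to the
    # compiled spring kernel
    cubic = params.k1 * dl + params.k2 * dl * dl * dl
    A = params.k1 * dl_c + params.k2 * dl_c**3
    B = params.k1 + 3.0 * params.k2 * dl_c**2
    linear = (A + B * (a - dl_c)) * np.sign(dl)
    out = np.where(a <= dl_c, cubic, linear)
    return out if out.ndim else float(out)


def spring_forces(system: ParticleSystem, springs: Springs,
                  params: MaterialParams, dl_c=None) -> np.ndarray:
    """Accumulated per-node spring forces (n, 3).

    Each spring applies a restoring pair: the force on node ``i`` points
    toward ``j`` when the spring is stretched, and ``j`` receives the exact
    negation, so total linear momentum is conserved.  Springs shorter than
    ``DEGENERATE_EPS`` contribute nothing (a warning is emitted).
    """
    x = system.x
    f = np.zeros_like(x)
    if len(springs) == 0:
        return f
    d = x[springs.i] - x[springs.j]
    length = np.linalg.norm(d, axis=1)
    degenerate = length < DEGENERATE_EPS
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate spring(s) skipped",
                      RuntimeWarning, stacklevel=2)
    safe = np.where(degenerate, 1.0, length)
    if dl_c is None:
        dl_c = params.crossover(springs.l0)
    mag = spring_scalar(length - springs.l0, params, dl_c=dl_c)
    mag = np.where(degenerate, 0.0, mag)
    pair = (-mag / safe)[:, None] * d  # restoring: toward j under stretch
    np.add.at(f, springs.i, pair)
    np.add.at(f, springs.j, -pair)
    return f


def damper_forces(system: ParticleSystem, params: MaterialParams) -> np.ndarray:
    """Viscoelastic damper force per node (n, 3), opposing velocity.

    ``f_i = -(b0 + b1*||x_i - x_rest,i||) * v_i``.  This is the literal
    force law; the solver integrates the same law implicitly for stability
    (see :mod:`softpbd.solver`), while this evaluation is used for probes,
    diagnostics and tests.
    """
    d = np.linalg.norm(system.x - system.x_rest, axis=1)
    return -(params.b0 + params.b1 * d)[:, None] * system.v


def damping_coefficients(system: ParticleSystem, params: MaterialParams) -> np.ndarray:
    """Per-node damper coefficient ``b0 + b1*||x - x_rest||`` (uN.s/mm)."""
    d = np.linalg.norm(system.x - system.x_rest, axis=1)
    return params.b0 + params.b1 * d
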