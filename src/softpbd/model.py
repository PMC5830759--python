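"""Simulation model container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["SimModel"]

#: Solver modes: the full integrated method, constraint projection only
#: (classical PBD limit: springs and dampers off) or springs/dampers only
#: (classical MSD limit: constraint projection off).
MODES = ("integrated", "pbd_only", "msd_only")


@dataclass
class SimModel:
    """Geometry + springs + constraints + boundary conditions + material.

    ``batch`` holds the persistent kernel constraints in projection order
    (overstretch limiters first, then tet-volume constraints);
    ``surface_volume`` is the optional single global enclosed-volume
    constraint of cavity models, projected between kernel sweeps.  Contact
    constraints are regenerated every step by the solver and are not stored
    here.
    """

    system: "ParticleSystem"
    springs: "Springs"
    batch: "ConstraintBatch"
    surface_volume: object = None
    material: object = None
    mesh: object = None
    collision: object = None
    bcs: list = field(default_factory=list)
    mode: str = "integrated"

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        # per-spring crossover elongation (cubic->linear), precomputed once
        if self.material is not None and len(self.springs):
            self.dl_c = np.ascontiguousarray(
                np.broadcast_to(self.material.crossover(self.springs.l0),
                                self.springs.l0.shape), dtype=np.float64)
        else:
            self.dl_c = None

    @property
    def springs_enabled(self) -> bool:
        return self.mode != "pbd_only"

    @property
    def constraints_enabled(self) -> bool:
        return self.mode != "msd_only"

    @property
    def n_nodes(self) -> int:
        return self.system.n

    def current_volume(self) -> float:
        """Mesh volume evaluated at the current node positions."""
        from .geometry import SurfaceMesh, TetMesh

        x = self.system.x
        n_mesh = len(self.mesh.vertices)
        if isinstance(self.mesh, TetMesh):
            p = x[: n_mesh][self.mesh.tets]
            return float(np.einsum(
                "ij,ij->i",
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                p[:, 3] - p[:, 0]).sum() / 6.0)
        if isinstance(self.mesh, SurfaceMesh):
            t = self.mesh.triangles
            a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
            return float(np.einsum("ij,ij->i", np.cross(a, b), c).sum() / 6.0)
        raise InvalidArgumentError("model has no mesh to measure")

    def add_static_nodes(self, positions) -> np.ndarray:
        """Append immovable nodes (w = 0), e.g. a collision floor.

        Returns the indices of the new nodes.  Springs, constraints and the
        mesh are untouched; the nodes exist only as collision geometry or
        anchors.
        """
        from .forces import ParticleSystem

        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        s = self.system
        start = s.n
        self.system = ParticleSystem(
            x=np.vstack([s.x, positions]),
            x_prev=np.vstack([s.x_prev, positions]),
            v=np.vstack([s.v, np.zeros_like(positions)]),
            w=np.concatenate([s.w, np.zeros(len(positions))]),
            x_rest=np.vstack([s.x_rest, positions]),
        )
        return np.arange(start, start + len(positions))
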