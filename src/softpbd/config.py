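"""YAML scenario configuration.

A scenario file describes geometry, material, solver settings, boundary
conditions and probes:

.. code-block:: yaml

    geometry: {kind: cube, edge_length: 60, divisions: 6}
    material: {k1: 0.25, k2: 10, b0: 2, b1: 1000, alpha: 0, k_ratio: 0.5}
    model:    {preset: entity, overstretch: true, mode: integrated}
    solver:   {dt: 0.005, iterations: 10, gravity: [0, 0, -9810]}
    duration: 2.0
    boundary_conditions:
      - {kind: fixed, nodes: {select: face, axis: 2, side: min}}
      - {kind: prescribed_velocity, nodes: {select: top_center},
         value: [0, 0, -10]}
    probes:
      - {kind: displacement, node: {select: top_center},
         direction: [0, 0, -1]}
      - {kind: volume}

Node sets may be explicit index lists or named selectors (``face`` with
``axis``/``side``, ``top_center``, ``all``).  Geometry kinds: ``cube``,
``beam``, ``icosphere``, or ``surface_file`` / ``tet_file`` with a
``path``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import InvalidArgumentError
from .forces import MaterialParams
from .geometry import (build_model, face_nodes, generate_beam,
                       generate_cube_lattice, generate_icosphere,
                       read_surface_mesh, read_tet_mesh, top_center_node)
from .solver import BoundaryCondition, SolverConfig

__all__ = ["Scenario", "load_scenario", "load_scenario_dict"]


@dataclass
class Scenario:
    """A fully assembled scenario: model, solver config, duration, probes."""

    model: object
    solver: SolverConfig
    duration: float
    probes: list
    probe_names: list
    raw: dict


def _build_geometry(spec: dict):
    kind = spec.get("kind")
    if kind == "cube":
        return generate_cube_lattice(spec.get("edge_length", 60.0),
                                     int(spec.get("divisions", 6)))
    if kind == "beam":
        return generate_beam(spec.get("lengths", [60.0, 20.0, 20.0]),
                             spec.get("divisions", [6, 2, 2]))
    if kind == "icosphere":
        return generate_icosphere(spec.get("radius", 15.0),
                                  int(spec.get("subdivisions", 2)))
    if kind == "surface_file":
        return read_surface_mesh(spec["path"])
    if kind == "tet_file":
        return read_tet_mesh(spec["path"])
    raise InvalidArgumentError(f"unknown geometry kind {kind!r}")


def _resolve_nodes(spec, mesh):
    if isinstance(spec, dict):
        sel = spec.get("select")
        if sel == "face":
            return face_nodes(mesh, int(spec["axis"]), spec.get("side", "min"))
        if sel == "top_center":
            return np.array([top_center_node(mesh)])
        if sel == "all":
            return np.arange(len(mesh.vertices))
        raise InvalidArgumentError(f"unknown node selector {sel!r}")
    return np.atleast_1d(np.asarray(spec, dtype=np.int64))


def load_scenario_dict(cfg: dict) -> Scenario:
    """Assemble a :class:`Scenario` from a parsed configuration mapping."""
    mesh = _build_geometry(cfg.get("geometry", {}))
    mat_spec = dict(cfg.get("material", {}))
    material = MaterialParams(**mat_spec)
    model_spec = dict(cfg.get("model", {}))
    mode = model_spec.pop("mode", "integrated")
    model = build_model(mesh, material,
                        preset=model_spec.get("preset"),
                        overstretch=model_spec.get("overstretch", True),
                        density=model_spec.get("density", 1.0e-3),
                        total_mass=model_spec.get("total_mass"))
    model.mode = mode

    for bc in cfg.get("boundary_conditions", []):
        nodes = _resolve_nodes(bc["nodes"], mesh)
        schedule = tuple(bc["schedule"]) if "schedule" in bc else None
        model.bcs.append(BoundaryCondition(
            bc["kind"], nodes, value=np.asarray(bc.get("value", [0, 0, 0]),
                                                dtype=float),
            schedule=schedule))

    probes, names = [], []
    for p in cfg.get("probes", []):
        kind = p["kind"]
        if kind in ("displacement", "reaction_force"):
            node = int(_resolve_nodes(p["node"], mesh)[0])
            probes.append((kind, node, np.asarray(p["direction"], float)))
        elif kind == "node_position":
            probes.append((kind, int(_resolve_nodes(p["node"], mesh)[0])))
        else:
            probes.append((kind,))
        names.append(p.get("name", kind))

    solver_spec = dict(cfg.get("solver", {}))
    solver = SolverConfig(dt=solver_spec.get("dt", 0.005),
                          iterations=int(solver_spec.get("iterations", 10)),
                          gravity=solver_spec.get("gravity", [0.0, 0.0, 0.0]))
    return Scenario(model=model, solver=solver,
                    duration=float(cfg.get("duration", 1.0)),
                    probes=probes, probe_names=names, raw=cfg)


def load_scenario(path) -> Scenario:
    """Load a YAML scenario file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"scenario file {path} is not a mapping")
    return load_scenario_dict(cfg)
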