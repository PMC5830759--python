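"""Mesh generation, I/O and model assembly.

Two mesh flavours mirror the two organ archetypes the simulator targets:

* ``TetMesh`` — a tetrahedral volume mesh for *entity* (solid) organs such
  as the liver; every tetrahedron carries a local volume constraint.
* ``SurfaceMesh`` — a closed, outward-oriented triangle mesh for *cavity*
  (hollow) organs such as the gallbladder; one global enclosed-volume
  constraint covers the whole surface.

Generators produce the parameterized primitives the bundled experiments
use (cube lattice, cantilever beam, icosphere); readers accept OBJ/OFF
surface meshes (via trimesh) and TetGen ``.node``/``.ele`` tet meshes.
All internal indexing is 0-based; TetGen's on-disk index base is converted
at the reader/writer boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, MeshParseError, TopologyError

__all__ = [
    "SurfaceMesh",
    "TetMesh",
    "generate_cube_lattice",
    "generate_beam",
    "generate_icosphere",
    "read_surface_mesh",
    "read_tet_mesh",
    "write_surface_mesh",
    "write_tet_mesh",
    "mesh_volume",
    "unique_edges",
    "build_model",
]


# ---------------------------------------------------------------------------
# mesh types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) mm, ``triangles`` (m, 3).

    Triangle winding encodes outward normals.  For closed meshes every
    undirected edge is shared by exactly two triangles with opposite
    directed orientation.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidArgumentError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise InvalidArgumentError("triangles must be (m, 3)")
        if len(self.triangles) and (self.triangles.min() < 0
                                    or self.triangles.max() >= len(self.vertices)):
            raise InvalidArgumentError("triangle indices out of range")

    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly 2 triangles."""
        e = np.sort(_triangle_edges(self.triangles), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(len(e)) and bool(np.all(counts == 2))


@dataclass
class TetMesh:
    """Tetrahedral volume mesh: ``vertices`` (n, 3) mm, ``tets`` (m, 4).

    Tets are oriented so their signed volume
    ``(1/6)((p2-p1) x (p3-p1)) . (p4-p1)`` is strictly positive.
    """

    vertices: np.ndarray
    tets: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidArgumentError("vertices must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise InvalidArgumentError("tets must be (m, 4)")
        if len(self.tets) and (self.tets.min() < 0
                               or self.tets.max() >= len(self.vertices)):
            raise InvalidArgumentError("tet indices out of range")

    def tet_volumes(self) -> np.ndarray:
        return _tet_volumes(self.vertices, self.tets)


def _triangle_edges(tris: np.ndarray) -> np.ndarray:
    return np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])


def _tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = verts[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

# 5-tet split of the unit cell, two mirror-image parities so shared faces of
# neighbouring cells carry the same diagonal (conforming lattice).  Corners
# are encoded as (dx, dy, dz) offsets; every tet is positively oriented.
_A, _B, _C, _D = (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)
_E, _F, _G, _H = (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)
_CELL_TETS = (
    # parity 0: four corner tets + central tet
    ((_A, _B, _C, _D), (_B, _E, _C, _H), (_B, _D, _F, _H),
     (_C, _G, _D, _H), (_B, _C, _D, _H)),
    # parity 1: x-mirror of parity 0, reordered to positive orientation
    ((_A, _B, _E, _F), (_C, _A, _E, _G), (_F, _A, _D, _G),
     (_H, _E, _F, _G), (_E, _A, _F, _G)),
)


def _box_lattice(lengths, divisions) -> TetMesh:
    lengths = np.asarray(lengths, dtype=float)
    divisions = np.asarray(divisions, dtype=int)
    if np.any(lengths <= 0):
        raise InvalidArgumentError("edge lengths must be positive")
    if np.any(divisions < 1):
        raise InvalidArgumentError("divisions must be >= 1")
    dx, dy, dz = (int(d) for d in divisions)
    xs = [np.linspace(0.0, lengths[a], divisions[a] + 1) for a in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def vid(i, j, k):
        return (i * (dy + 1) + j) * (dz + 1) + k

    tets = []
    for i in range(dx):
        for j in range(dy):
            for k in range(dz):
                parity = (i + j + k) % 2
                for tet in _CELL_TETS[parity]:
                    tets.append([vid(i + o[0], j + o[1], k + o[2]) for o in tet])
    return TetMesh(vertices=verts, tets=np.asarray(tets, dtype=np.int64))


def generate_cube_lattice(edge_length: float, divisions: int) -> TetMesh:
    """Regular cube lattice of ``(divisions+1)**3`` nodes, 5 tets per cell.

    The alternating-parity 5-tet split is conforming (neighbouring cells
    agree on face diagonals) and partitions the cube exactly, so the summed
    tet volume equals ``edge_length**3``.
    """
    if edge_length <= 0:
        raise InvalidArgumentError("edge_length must be positive")
    if divisions < 1:
        raise InvalidArgumentError("divisions must be >= 1")
    return _box_lattice([edge_length] * 3, [divisions] * 3)


def generate_beam(lengths, divisions) -> TetMesh:
    """Rectangular beam lattice (same 5-tet cell split as the cube)."""
    return _box_lattice(lengths, divisions)


def generate_icosphere(radius: float, subdivisions: int) -> SurfaceMesh:
    """Closed outward-oriented icosphere (12 vertices / 20 faces at level 0)."""
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    if subdivisions < 0:
        raise InvalidArgumentError("subdivisions must be >= 0")
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=int(subdivisions),
                                   radius=float(radius))
    return SurfaceMesh(vertices=np.asarray(m.vertices),
                       triangles=np.asarray(m.faces))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_surface_mesh(path, require_closed: bool = False) -> SurfaceMesh:
    """Read an OBJ or OFF triangle mesh.

    Raises :class:`MeshParseError` on unreadable input and
    :class:`TopologyError` if ``require_closed`` and the mesh is open.
    """
    import trimesh

    if not os.path.exists(path):
        raise MeshParseError(f"no such file: {path}")
    try:
        m = trimesh.load(str(path), process=False, force="mesh")
        verts = np.asarray(m.vertices, dtype=float)
        faces = np.asarray(m.faces, dtype=int)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshParseError(f"cannot parse surface mesh {path}: {exc}") from exc
    if verts.size == 0 or faces.size == 0:
        raise MeshParseError(f"no triangles found in {path}")
    mesh = SurfaceMesh(vertices=verts, triangles=faces)
    if require_closed and not mesh.is_closed():
        raise TopologyError(f"surface mesh {path} is not closed")
    return mesh


def write_surface_mesh(mesh: SurfaceMesh, path) -> None:
    """Write OBJ or OFF (by file extension) via trimesh."""
    import trimesh

    trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                    process=False).export(str(path))


def _read_numeric_rows(path, min_cols):
    """Parse a TetGen-style file into numeric rows, tracking line numbers."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            try:
                rows.append((lineno, [float(f) for f in fields]))
            except ValueError as exc:
                raise MeshParseError(f"non-numeric field in {path}", line=lineno) from exc
    if not rows:
        raise MeshParseError(f"empty file {path}")
    return rows


def read_tet_mesh(path) -> TetMesh:
    """Read a TetGen ``.node``/``.ele`` pair (either filename or the stem).

    On-disk indices may start at 0 or 1 (TetGen convention: the first listed
    node defines the base); they are converted to 0-based.  Tets with
    non-positive signed volume are reoriented.
    """
    base, ext = os.path.splitext(str(path))
    if ext not in (".node", ".ele", ""):
        base = str(path)
    node_path, ele_path = base + ".node", base + ".ele"
    for p in (node_path, ele_path):
        if not os.path.exists(p):
            raise MeshParseError(f"no such file: {p}")

    rows = _read_numeric_rows(node_path, 4)
    lineno, header = rows[0]
    if len(header) < 1:
        raise MeshParseError("bad .node header", line=lineno)
    n_nodes = int(header[0])
    body = rows[1:]
    if len(body) < n_nodes:
        raise MeshParseError(
            f"truncated .node file: header promises {n_nodes} nodes, "
            f"found {len(body)}", line=body[-1][0] if body else lineno)
    ids, coords = [], []
    for lineno, fields in body[:n_nodes]:
        if len(fields) < 4:
            raise MeshParseError("node row needs id + 3 coordinates", line=lineno)
        ids.append(int(fields[0]))
        coords.append(fields[1:4])
    first_index = min(ids)
    if first_index not in (0, 1):
        raise MeshParseError(f".node indices must start at 0 or 1, got {first_index}")
    order = np.argsort(ids)
    verts = np.asarray(coords, dtype=float)[order]

    rows = _read_numeric_rows(ele_path, 5)
    lineno, header = rows[0]
    n_tets = int(header[0])
    body = rows[1:]
    if len(body) < n_tets:
        raise MeshParseError(
            f"truncated .ele file: header promises {n_tets} tets, "
            f"found {len(body)}", line=body[-1][0] if body else lineno)
    tets = []
    for lineno, fields in body[:n_tets]:
        if len(fields) < 5:
            raise MeshParseError("ele row needs id + 4 node indices", line=lineno)
        tet = [int(f) - first_index for f in fields[1:5]]
        if min(tet) < 0 or max(tet) >= len(verts):
            raise MeshParseError("tet node index out of range", line=lineno)
        tets.append(tet)
    tets = np.asarray(tets, dtype=np.int64)
    vols = _tet_volumes(verts, tets)
    flip = vols < 0
    if flip.any():
        tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    if np.any(_tet_volumes(verts, tets) <= 0):
        raise TopologyError("degenerate (zero-volume) tetrahedron in mesh")
    return TetMesh(vertices=verts, tets=tets)


def write_tet_mesh(mesh: TetMesh, base_path) -> None:
    """Write TetGen ``.node``/``.ele`` files (1-based on disk)."""
    base = str(base_path)
    if base.endswith(".node") or base.endswith(".ele"):
        base = os.path.splitext(base)[0]
    with open(base + ".node", "w") as fh:
        fh.write(f"{len(mesh.vertices)} 3 0 0\n")
        for idx, p in enumerate(mesh.vertices, start=1):
            fh.write(f"{idx} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(base + ".ele", "w") as fh:
        fh.write(f"{len(mesh.tets)} 4 0\n")
        for idx, t in enumerate(mesh.tets, start=1):
            fh.write(f"{idx} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}\n")


# ---------------------------------------------------------------------------
# derived quantities and model assembly
# ---------------------------------------------------------------------------

def mesh_volume(mesh) -> float:
    """Enclosed volume (mm^3).

    Tet meshes sum signed tet volumes; closed surface meshes use the
    divergence theorem ``V = (1/6) sum_t (p1 x p2) . p3`` over triangles.
    Raises :class:`TopologyError` for an open surface mesh.
    """
    if isinstance(mesh, TetMesh):
        return float(mesh.tet_volumes().sum())
    if isinstance(mesh, SurfaceMesh):
        if not mesh.is_closed():
            raise TopologyError("surface mesh is not closed; volume undefined")
        p = mesh.vertices[mesh.triangles]
        return float(np.einsum("ij,ij->i",
                               np.cross(p[:, 0], p[:, 1]), p[:, 2]).sum() / 6.0)
    raise InvalidArgumentError(f"not a mesh: {type(mesh).__name__}")


def unique_edges(mesh) -> np.ndarray:
    """Deduplicated undirected edges (k, 2) of a tet or surface mesh."""
    if isinstance(mesh, TetMesh):
        t = mesh.tets
        e = np.concatenate([t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]],
                            t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]])
    elif isinstance(mesh, SurfaceMesh):
        e = _triangle_edges(mesh.triangles)
    else:
        raise InvalidArgumentError(f"not a mesh: {type(mesh).__name__}")
    return np.unique(np.sort(e, axis=1), axis=0)


#: Default mass density, g/mm^3 (water-like, appropriate for soft tissue).
DEFAULT_DENSITY = 1.0e-3


def build_model(mesh, material, preset: str | None = None,
                overstretch: bool = True, density: float = DEFAULT_DENSITY,
                total_mass: float | None = None):
    """Assemble a :class:`~softpbd.model.SimModel` from a mesh.

    ``preset`` selects the organ archetype: ``"entity"`` (tet mesh; one
    volume constraint per tetrahedron) or ``"cavity"`` (closed surface
    mesh; a single global enclosed-volume constraint).  It defaults to the
    archetype matching the mesh type.  One spring is created per unique
    mesh edge with rest length equal to the initial edge length, plus one
    overstretch limiter per spring when ``overstretch`` is on.

    Node masses are a uniform lumping of ``total_mass`` (defaulting to
    ``density * rest volume``).
    """
    from .constraints import ConstraintBatch, SurfaceVolumeConstraint
    from .forces import ParticleSystem, Springs
    from .model import SimModel

    if preset is None:
        preset = "entity" if isinstance(mesh, TetMesh) else "cavity"
    if preset not in ("entity", "cavity"):
        raise InvalidArgumentError(f"unknown preset {preset!r}")
    if preset == "entity" and not isinstance(mesh, TetMesh):
        raise InvalidArgumentError("entity preset requires a TetMesh")
    if preset == "cavity" and not isinstance(mesh, SurfaceMesh):
        raise InvalidArgumentError("cavity preset requires a SurfaceMesh")

    volume = mesh_volume(mesh)
    if total_mass is None:
        total_mass = density * abs(volume)
    n = len(mesh.vertices)
    system = ParticleSystem.from_positions(mesh.vertices,
                                           np.full(n, total_mass / n))

    edges = unique_edges(mesh)
    l0 = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]],
                        axis=1)
    springs = Springs(edges[:, 0], edges[:, 1], l0)

    batch = ConstraintBatch()
    if overstretch:
        for (a, b), rest in zip(edges, l0):
            batch.add_overstretch(int(a), int(b), float(rest),
                                  material.k_ratio * float(rest))
    surface_volume = None
    if preset == "entity":
        vols = mesh.tet_volumes()
        if np.any(vols <= 0):
            raise InvalidArgumentError("tet mesh has non-positive volumes")
        for tet, v0 in zip(mesh.tets, vols):
            batch.add_tet_volume(*(int(i) for i in tet), float(v0),
                                 alpha=material.alpha)
    else:
        if not mesh.is_closed():
            raise TopologyError("cavity preset requires a closed surface mesh")
        surface_volume = SurfaceVolumeConstraint(
            triangles=mesh.triangles.copy(), rest=volume, alpha=material.alpha)

    return SimModel(system=system, springs=springs, batch=batch,
                    surface_volume=surface_volume, material=material,
                    mesh=mesh)


# --- node selection helpers (used by scenarios and config files) -----------

def face_nodes(mesh, axis: int, side: str, tol: float = 1e-9) -> np.ndarray:
    """Node indices on the min or max face of a lattice along ``axis``."""
    coords = mesh.vertices[:, axis]
    target = coords.min() if side == "min" else coords.max()
    span = max(coords.max() - coords.min(), 1.0)
    return np.flatnonzero(np.abs(coords - target) <= tol * span + tol)


def nearest_node(mesh, point) -> int:
    """Index of the mesh vertex closest to ``point``."""
    return int(np.argmin(np.linalg.norm(
        mesh.vertices - np.asarray(point, dtype=float), axis=1)))


def top_center_node(mesh) -> int:
    """Node at the centre of the upper (+z) face — the rheometry test point."""
    v = mesh.vertices
    top = v[:, 2].max()
    center = [(v[:, 0].min() + v[:, 0].max()) / 2,
              (v[:, 1].min() + v[:, 1].max()) / 2, top]
    idx = nearest_node(mesh, center)
    if abs(v[idx, 2] - top) > 1e-9 * max(top, 1.0) or \
       np.linalg.norm(v[idx] - center) > 1e-9 * max(top, 1.0):
        raise InvalidArgumentError(
            "no exact upper-face centre node; use even division counts")
    return idx
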