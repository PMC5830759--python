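"""Spatial-hash broad phase and sphere/triangle narrow phase.

Simulated bodies expose two primitive kinds: spheres attached to nodes and
collision triangles over node triples.  The broad phase registers every
primitive's axis-aligned bounding box (AABB) in the integer grid cells it
overlaps, hashes cell coordinates into a bucket table with the classic
three-prime XOR hash, collects same-bucket pairs once, and re-checks AABB
overlap before handing pairs to the narrow phase (distinct cells may share
a bucket, so the bucket test alone is a superset).

The narrow phase emits unilateral contact constraints (compliance 0) only
on strict penetration; separated or exactly touching primitives generate
nothing.  Triangle-triangle pairs are resolved as three vertex-triangle
tests of the first triangle's corners against the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .constraints import Constraint, ConstraintBatch, KIND_CONTACT_SS, KIND_CONTACT_VT
from .errors import InvalidArgumentError

__all__ = [
    "CollisionPrimitive", "AABB", "CollisionSpec",
    "compute_aabb", "hash_cell", "broad_phase",
    "narrow_sphere_sphere", "narrow_sphere_triangle", "detect_contacts",
]

_P1, _P2, _P3 = 73856093, 19349663, 83492791


@dataclass(frozen=True)
class CollisionPrimitive:
    """A collision primitive: ``sphere`` (one node + radius) or ``triangle``."""

    kind: str
    nodes: tuple
    radius: float = 0.0
    owner: int = 0

    def __post_init__(self):
        if self.kind == "sphere":
            if len(self.nodes) != 1 or self.radius <= 0:
                raise InvalidArgumentError("sphere needs 1 node and radius > 0")
        elif self.kind == "triangle":
            if len(set(self.nodes)) != 3:
                raise InvalidArgumentError("triangle needs 3 distinct nodes")
        else:
            raise InvalidArgumentError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class AABB:
    """Axis-aligned bounding box (componentwise min <= max)."""

    min: np.ndarray
    max: np.ndarray

    def overlaps(self, other: "AABB") -> bool:
        return bool(np.all(self.min <= other.max) and np.all(other.min <= self.max))


def compute_aabb(primitive: CollisionPrimitive, positions, margin: float = 0.0) -> AABB:
    """AABB of a primitive at the given node positions, grown by ``margin``."""
    x = np.asarray(positions, float)
    if primitive.kind == "sphere":
        c = x[primitive.nodes[0]]
        r = primitive.radius + margin
        return AABB(min=c - r, max=c + r)
    pts = x[list(primitive.nodes)]
    return AABB(min=pts.min(axis=0) - margin, max=pts.max(axis=0) + margin)


def hash_cell(i: int, j: int, k: int, table_size: int) -> int:
    """Three-prime XOR spatial hash of integer cell coordinates.

    ``((i*73856093) xor (j*19349663) xor (k*83492791)) mod table_size``,
    mapped to the non-negative range.
    """
    if table_size < 1:
        raise InvalidArgumentError("table_size must be >= 1")
    return ((int(i) * _P1) ^ (int(j) * _P2) ^ (int(k) * _P3)) % table_size


def broad_phase(primitives, positions, cell_size: float = None,
                table_size: int = None, margin: float = 0.0):
    """Candidate pairs of primitive indices with overlapping AABBs.

    Pairs are emitted once per unordered pair; self-pairs and pairs
    sharing a node are excluded.  Bucket collisions from the hash are
    filtered by an explicit AABB overlap re-check, so the result equals
    brute-force all-pairs AABB intersection.
    """
    if cell_size is not None and cell_size <= 0:
        raise InvalidArgumentError("cell_size must be positive")
    aabbs = [compute_aabb(p, positions, margin) for p in primitives]
    if cell_size is None:
        radii = [p.radius for p in primitives if p.kind == "sphere"]
        cell_size = 2.0 * float(np.mean(radii)) if radii else 1.0
        if cell_size <= 0:
            cell_size = 1.0
    if table_size is None:
        table_size = max(2 * len(primitives), 1)

    buckets: dict[int, list[int]] = {}
    for idx, box in enumerate(aabbs):
        lo = np.floor(box.min / cell_size).astype(np.int64)
        hi = np.floor(box.max / cell_size).astype(np.int64)
        seen = set()
        # inlined hash_cell (hot loop: wide primitives span many cells)
        for ci in range(lo[0], hi[0] + 1):
            hx = ci * _P1
            for cj in range(lo[1], hi[1] + 1):
                hxy = hx ^ (cj * _P2)
                for ck in range(lo[2], hi[2] + 1):
                    h = (hxy ^ (ck * _P3)) % table_size
                    if h not in seen:
                        seen.add(h)
                        buckets.setdefault(h, []).append(idx)

    # flat float bounds for cheap scalar overlap tests in the pair loop
    bounds = [(float(b.min[0]), float(b.min[1]), float(b.min[2]),
               float(b.max[0]), float(b.max[1]), float(b.max[2]))
              for b in aabbs]
    node_sets = [set(p.nodes) for p in primitives]
    tested = set()  # each unordered pair examined once, whatever the bucket
    pairs = []
    for members in buckets.values():
        for a, b in combinations(members, 2):
            if a > b:
                a, b = b, a
            key = (a, b)
            if key in tested:
                continue
            tested.add(key)
            if node_sets[a] & node_sets[b]:
                continue
            la = bounds[a]
            lb = bounds[b]
            if (la[0] <= lb[3] and lb[0] <= la[3]
                    and la[1] <= lb[4] and lb[1] <= la[4]
                    and la[2] <= lb[5] and lb[2] <= la[5]):
                pairs.append(key)
    return sorted(pairs)


def narrow_sphere_sphere(q, p, r1: float, r2: float, i: int = 0, j: int = 1):
    """Contact constraint for two spheres, or None without strict penetration.

    The contact is a unilateral distance constraint with rest = r1 + r2 and
    compliance 0 between nodes ``i`` (centre q) and ``j`` (centre p).
    Coincident centres are reported with a warning; the caller is expected
    to separate them along a fixed axis before projection.
    """
    d = float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))
    if d >= r1 + r2:
        return None
    if d < 1e-9:
        warnings.warn("coincident sphere centres in contact", RuntimeWarning,
                      stacklevel=2)
    return Constraint(kind=KIND_CONTACT_SS, node_ids=(i, j), rest=r1 + r2,
                      alpha=0.0, unilateral=True)


def narrow_sphere_triangle(q, r: float, p1, p2, p3,
                           ids=(0, 1, 2, 3)):
    """Vertex-triangle contact constraint, or None.

    Fires only when the signed plane distance of the sphere centre is below
    ``r`` *and* the centre's in-plane projection falls inside the triangle
    (no edge/vertex regions).  Degenerate triangles are skipped.
    """
    q, p1, p2, p3 = (np.asarray(v, float) for v in (q, p1, p2, p3))
    e1, e2 = p2 - p1, p3 - p1
    n = np.cross(e1, e2)
    nn = float(np.linalg.norm(n))
    if nn < 1e-12:
        warnings.warn("degenerate collision triangle skipped", RuntimeWarning,
                      stacklevel=2)
        return None
    nhat = n / nn
    h = float((q - p1) @ nhat)
    if h >= r:
        return None
    proj = q - h * nhat
    a11, a12, a22 = e1 @ e1, e1 @ e2, e2 @ e2
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-18:
        return None
    dt_ = proj - p1
    b2 = (a22 * (e1 @ dt_) - a12 * (e2 @ dt_)) / det
    b3 = (a11 * (e2 @ dt_) - a12 * (e1 @ dt_)) / det
    if b2 < 0.0 or b3 < 0.0 or b2 + b3 > 1.0:
        return None
    return Constraint(kind=KIND_CONTACT_VT, node_ids=tuple(ids), rest=r,
                      alpha=0.0, unilateral=True)


@dataclass
class CollisionSpec:
    """Which nodes/faces of a model participate in collision.

    ``sphere_nodes``/``sphere_radii`` attach spheres to nodes;
    ``triangles`` lists collision faces as node triples (typically static
    geometry such as a floor, with fixed nodes).  ``self_collision``
    enables sphere-sphere tests between spheres of the same group.
    """

    sphere_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    sphere_radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    triangles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    sphere_groups: np.ndarray | None = None
    self_collision: bool = False
    cell_size: float | None = None
    table_size: int | None = None
    margin: float = 0.0

    def __post_init__(self):
        self.sphere_nodes = np.asarray(self.sphere_nodes, dtype=np.int64)
        self.sphere_radii = np.broadcast_to(
            np.asarray(self.sphere_radii, dtype=float),
            self.sphere_nodes.shape).copy()
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    def primitives(self):
        prims = [CollisionPrimitive("sphere", (int(n),), float(r),
                                    owner=int(g))
                 for n, r, g in zip(
                     self.sphere_nodes, self.sphere_radii,
                     self.sphere_groups if self.sphere_groups is not None
                     else np.zeros(len(self.sphere_nodes), int))]
        prims += [CollisionPrimitive("triangle", tuple(int(i) for i in t),
                                     owner=-1)
                  for t in self.triangles]
        return prims


def detect_contacts(x, spec: CollisionSpec) -> ConstraintBatch:
    """Run broad + narrow phase at positions ``x``; emit contact batch.

    Sphere-sphere contacts between spheres of the same group are skipped
    unless ``spec.self_collision`` is set.  Coincident sphere centres are
    separated along +x by a nominal offset before the constraint is built.
    """
    batch = ConstraintBatch()
    prims = spec.primitives()
    if not prims:
        return batch
    pairs = broad_phase(prims, x, cell_size=spec.cell_size,
                        table_size=spec.table_size, margin=spec.margin)
    for a, b in pairs:
        pa, pb = prims[a], prims[b]
        if pa.kind == "sphere" and pb.kind == "sphere":
            if not spec.self_collision and pa.owner == pb.owner and \
                    pa.owner >= 0:
                continue
            i, j = pa.nodes[0], pb.nodes[0]
            qa, qb = x[i], x[j]
            if np.linalg.norm(qa - qb) < 1e-9:
                qa = qa + np.array([1e-6 * (pa.radius + pb.radius), 0.0, 0.0])
            con = narrow_sphere_sphere(qa, qb, pa.radius, pb.radius, i=i, j=j)
            if con is not None:
                batch.add_contact_ss(i, j, con.rest)
        elif pa.kind == "sphere" or pb.kind == "sphere":
            s, t = (pa, pb) if pa.kind == "sphere" else (pb, pa)
            i = s.nodes[0]
            t1, t2, t3 = t.nodes
            con = narrow_sphere_triangle(x[i], s.radius, x[t1], x[t2], x[t3],
                                         ids=(i, t1, t2, t3))
            if con is not None:
                batch.add_contact_vt(i, t1, t2, t3, s.radius)
        else:  # triangle-triangle: three vertex-triangle tests
            for i in pa.nodes:
                t1, t2, t3 = pb.nodes
                con = narrow_sphere_triangle(x[i], 0.0, x[t1], x[t2], x[t3],
                                             ids=(i, t1, t2, t3))
                if con is not None:
                    batch.add_contact_vt(i, t1, t2, t3, 0.0)
    return batch


def floor_triangles(z: float = 0.0, half_extent: float = 1000.0,
                    center=(0.0, 0.0)):
    """Vertex positions and faces of a two-triangle floor at height ``z``.

    Returns ``(positions (4,3), faces (2,3))`` with faces wound so the
    normal points up (+z); face indices are local (0..3) and must be offset
    by the caller after appending the vertices as static nodes.
    """
    cx, cy = center
    h = half_extent
    pos = np.array([[cx - h, cy - h, z], [cx + h, cy - h, z],
                    [cx + h, cy + h, z], [cx - h, cy + h, z]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return pos, faces
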