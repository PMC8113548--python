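"""Foundational geometry: triangulated surfaces, rigid transforms, distance queries.

All geometry is expressed in millimetres, the natural scale for craniofacial
surgery where guidance thresholds and reported errors are of order 1 mm.

The two workhorse queries — closest point on a triangle mesh and signed
distance to an oriented surface — are implemented here with a KD-tree
candidate prefilter that is exactly equivalent to exhaustive per-triangle
minimisation: the prefilter only discards triangles that provably cannot
contain the minimiser, so accelerated and brute-force answers are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "EmptyMeshError",
    "FrameMismatchError",
    "TriMesh",
    "RigidTransform",
    "Plane",
    "compose",
    "invert",
    "apply",
    "closest_point_on_mesh",
    "signed_distance",
]

# Load-time mesh hygiene: STL files routinely duplicate vertices per facet and
# contain sliver facets; these tolerances (mm, mm^2) weld and drop them.
WELD_TOLERANCE_MM = 1e-6
DEGENERATE_AREA_MM2 = 1e-12

_ORTHONORMALITY_TOL = 1e-9


class GeometryError(ValueError):
    """Base class for geometry contract violations."""


class EmptyMeshError(GeometryError):
    """Raised when a distance query is made against a mesh with no faces."""


class FrameMismatchError(GeometryError):
    """Raised when rigid transforms are chained across disagreeing frames."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion mapping points from ``source_frame`` to ``target_frame``.

    Stored as a 3x3 rotation matrix and a translation vector in mm.  The
    rotation must be orthonormal with determinant +1 (no reflections: tracked
    instruments and anatomy never mirror).
    """

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str = "a"
    target_frame: str = "b"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise GeometryError("non-finite rigid transform")
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHONORMALITY_TOL:
            raise GeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHONORMALITY_TOL:
            raise GeometryError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, frame: str = "a", target: str | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame, target if target is not None else frame)

    @classmethod
    def from_quat(
        cls,
        quat_wxyz: np.ndarray,
        translation: np.ndarray,
        source_frame: str = "a",
        target_frame: str = "b",
    ) -> "RigidTransform":
        """Build from a unit quaternion in (w, x, y, z) order plus translation."""
        from scipy.spatial.transform import Rotation

        w, x, y, z = np.asarray(quat_wxyz, dtype=float)
        R = Rotation.from_quat([x, y, z, w]).as_matrix()
        return cls(R, translation, source_frame, target_frame)

    def to_quat(self) -> np.ndarray:
        """Return the rotation as a unit quaternion (w, x, y, z)."""
        from scipy.spatial.transform import Rotation

        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        return np.array([w, x, y, z])

    # -- algebra ------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (…,3) through rotation then translation."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``other ∘ self``: first this transform, then ``other``."""
        return compose(self, other)

    def invert(self) -> "RigidTransform":
        return invert(self)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def is_close(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )


def compose(t_ab: RigidTransform, t_bc: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps ``t_ab.source_frame`` to ``t_bc.target_frame``.

    Raises :class:`FrameMismatchError` when the intermediate frames disagree.
    """
    if t_ab.target_frame != t_bc.source_frame:
        raise FrameMismatchError(
            f"cannot chain {t_ab.source_frame}->{t_ab.target_frame} "
            f"with {t_bc.source_frame}->{t_bc.target_frame}"
        )
    R = t_bc.rotation @ t_ab.rotation
    # re-orthonormalise to keep long chains within the rigidity tolerance
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:  # numerically impossible for proper inputs, but guard
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    t = t_bc.rotation @ t_ab.translation + t_bc.translation
    return RigidTransform(R, t, t_ab.source_frame, t_bc.target_frame)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse motion; source and target frames swap."""
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation, t.target_frame, t.source_frame)


def apply(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(points)


# ---------------------------------------------------------------------------
# Planes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise GeometryError("plane normal must be non-zero and finite")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Householder reflection of points across the plane."""
        pts = np.asarray(points, dtype=float)
        d = self.signed_distance(pts)
        return pts - 2.0 * np.outer(np.atleast_1d(d), self.normal).reshape(pts.shape)


# ---------------------------------------------------------------------------
# Triangle meshes
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """A triangulated surface in image space (mm) with optional region tags.

    ``face_tags`` maps a region name (e.g. ``"surgical_area"``, ``"unchanged"``)
    to an integer array of face indices; ``vertex_tags`` does the same for
    vertices.  Tags are how the planner marks the resection region and how the
    evaluator knows which part of the skull was left untouched.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_tags: dict[str, np.ndarray] = field(default_factory=dict)
    vertex_tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("mesh vertices must be finite")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise GeometryError("face indices out of range")
        self.face_tags = {k: np.asarray(v, dtype=np.int64) for k, v in self.face_tags.items()}
        self.vertex_tags = {k: np.asarray(v, dtype=np.int64) for k, v in self.vertex_tags.items()}
        self._cache: dict[str, object] = {}

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "TriMesh":
        """Load an STL/PLY/OBJ surface, welding duplicate vertices and dropping
        degenerate faces."""
        tm = _trimesh.load(str(path), force="mesh", process=True)
        return cls.from_trimesh(tm)

    @classmethod
    def from_trimesh(cls, tm: "_trimesh.Trimesh") -> "TriMesh":
        tm = tm.copy()
        tm.merge_vertices(digits_vertex=int(-np.log10(WELD_TOLERANCE_MM)))
        keep = tm.area_faces > DEGENERATE_AREA_MM2
        tm.update_faces(keep)
        tm.remove_unreferenced_vertices()
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def to_trimesh(self) -> "_trimesh.Trimesh":
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def save(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))

    # -- derived quantities (cached) ----------------------------------------

    def _get(self, key: str, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        return self._get("triangles", lambda: self.vertices[self.faces])

    @property
    def face_normals(self) -> np.ndarray:
        def _compute():
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            return n / np.where(norms > 0, norms, 1.0)

        return self._get("face_normals", _compute)

    @property
    def face_areas(self) -> np.ndarray:
        def _compute():
            tri = self.triangles
            return 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )

        return self._get("face_areas", _compute)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted pseudonormals (the correct weighting for inside/outside
        classification at vertices of a closed mesh)."""

        def _compute():
            tri = self.triangles
            acc = np.zeros_like(self.vertices)
            for corner in range(3):
                a = tri[:, corner]
                b = tri[:, (corner + 1) % 3]
                c = tri[:, (corner + 2) % 3]
                u = b - a
                v = c - a
                cu = u / np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-300)
                cv = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
                ang = np.arccos(np.clip(np.sum(cu * cv, axis=1), -1.0, 1.0))
                np.add.at(acc, self.faces[:, corner], ang[:, None] * self.face_normals)
            norms = np.linalg.norm(acc, axis=1, keepdims=True)
            return acc / np.where(norms > 0, norms, 1.0)

        return self._get("vertex_normals", _compute)

    @property
    def vertex_areas(self) -> np.ndarray:
        """One third of the area of each incident face, per vertex (barycentric
        lumping, so vertex areas sum to the surface area)."""

        def _compute():
            va = np.zeros(len(self.vertices))
            third = self.face_areas / 3.0
            for corner in range(3):
                np.add.at(va, self.faces[:, corner], third)
            return va

        return self._get("vertex_areas", _compute)

    @property
    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for a closed outward-oriented mesh."""
        tri = self.triangles
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0

    def _edge_face_map(self) -> dict[tuple[int, int], list[int]]:
        def _compute():
            m: dict[tuple[int, int], list[int]] = {}
            for fi, (a, b, c) in enumerate(self.faces):
                for e in ((a, b), (b, c), (c, a)):
                    key = (min(e), max(e))
                    m.setdefault(key, []).append(fi)
            return m

        return self._get("edge_face_map", _compute)

    def _face_tree(self) -> tuple[cKDTree, float]:
        def _compute():
            centroids = self.triangles.mean(axis=1)
            half_diam = np.linalg.norm(
                self.triangles - centroids[:, None, :], axis=2
            ).max()
            return cKDTree(centroids), float(half_diam)

        return self._get("face_tree", _compute)

    def transformed(self, t: RigidTransform) -> "TriMesh":
        return TriMesh(t.apply(self.vertices), self.faces.copy(),
                       {k: v.copy() for k, v in self.face_tags.items()},
                       {k: v.copy() for k, v in self.vertex_tags.items()})

    def submesh(self, face_indices: np.ndarray) -> "TriMesh":
        """Extract the faces listed (re-indexing vertices)."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        faces = self.faces[face_indices]
        used, inverse = np.unique(faces, return_inverse=True)
        return TriMesh(self.vertices[used], inverse.reshape(-1, 3))


# ---------------------------------------------------------------------------
# Closest-point and signed-distance queries
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point to ``p`` on each triangle of ``tri`` (n,3,3).

    Vectorised region classification (Ericson, Real-Time Collision Detection).
    Returns (closest points (n,3), squared distances (n,)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge regions
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    diff = out - p
    return out, np.einsum("ij,ij->i", diff, diff)


def closest_point_brute(p: np.ndarray, mesh: TriMesh) -> tuple[np.ndarray, float, int]:
    """Exhaustive per-triangle minimisation — the reference oracle."""
    if mesh.n_faces == 0:
        raise EmptyMeshError("closest-point query against an empty mesh")
    pts, d2 = _closest_on_triangles(np.asarray(p, dtype=float), mesh.triangles)
    i = int(np.argmin(d2))
    return pts[i], float(np.sqrt(d2[i])), i


def closest_point_on_mesh(p: np.ndarray, mesh: TriMesh) -> tuple[np.ndarray, float, int]:
    """Closest point on the mesh surface to ``p``.

    Returns (point on surface, Euclidean distance in mm, face index).  Uses a
    KD-tree over face centroids to restrict the exact per-triangle test to
    faces whose centroid lies within d0 + h of the query, where d0 is the
    exact distance to the nearest-centroid face and h the largest
    centroid-to-vertex span: any face achieving the global minimum dmin ≤ d0
    has centroid distance ≤ dmin + h ≤ d0 + h, so no achiever is pruned and
    the result matches :func:`closest_point_brute` bit for bit.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("closest-point query against an empty mesh")
    p = np.asarray(p, dtype=float).reshape(3)
    tree, half_diam = mesh._face_tree()
    _, seed_face = tree.query(p)
    _, d2_seed = _closest_on_triangles(p, mesh.triangles[[seed_face]])
    d0 = float(np.sqrt(d2_seed[0]))
    candidates = tree.query_ball_point(p, d0 + half_diam + 1e-12)
    candidates = np.sort(np.asarray(candidates, dtype=np.int64))
    pts, d2 = _closest_on_triangles(p, mesh.triangles[candidates])
    i = int(np.argmin(d2))
    return pts[i], float(np.sqrt(d2[i])), int(candidates[i])


def closest_points_on_mesh(
    points: np.ndarray, mesh: TriMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched :func:`closest_point_on_mesh` over many query points.

    Runs the identical per-triangle arithmetic and candidate pruning as the
    single-point query in one vectorised pass, so each row of the result is
    bit-identical to the per-point call.  Returns (surface points (n,3),
    distances (n,), face indices (n,)).
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("closest-point query against an empty mesh")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tree, half_diam = mesh._face_tree()
    _, seed_faces = tree.query(pts)
    _, d2_seed = _closest_on_triangles(pts, mesh.triangles[seed_faces])
    radii = np.sqrt(d2_seed) + half_diam + 1e-12
    cand_lists = tree.query_ball_point(pts, radii)
    cand_lists = [np.sort(np.asarray(c, dtype=np.int64)) for c in cand_lists]
    counts = np.array([len(c) for c in cand_lists])
    flat_faces = np.concatenate(cand_lists)
    flat_pts = np.repeat(pts, counts, axis=0)
    cand_out, cand_d2 = _closest_on_triangles(flat_pts, mesh.triangles[flat_faces])

    out_pts = np.empty_like(pts)
    out_d = np.empty(len(pts))
    out_f = np.empty(len(pts), dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i in range(len(pts)):
        lo, hi = offsets[i], offsets[i + 1]
        j = lo + int(np.argmin(cand_d2[lo:hi]))
        out_pts[i] = cand_out[j]
        out_d[i] = np.sqrt(cand_d2[j])
        out_f[i] = flat_faces[j]
    return out_pts, out_d, out_f


def _pseudonormal_at(mesh: TriMesh, face_index: int, point: np.ndarray) -> np.ndarray:
    """Outward pseudonormal at a point on a face: face normal in the interior,
    edge-averaged normal on an edge, angle-weighted normal at a vertex."""
    a, b, c = mesh.faces[face_index]
    tri = mesh.vertices[[a, b, c]]
    # barycentric coordinates of the point
    v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
    v2 = point - tri[0]
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    if denom <= 0:
        return mesh.face_normals[face_index]
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    bary = np.array([1.0 - v - w, v, w])
    tol = 1e-9
    zero = bary < tol
    if zero.sum() == 0:
        return mesh.face_normals[face_index]
    if zero.sum() == 2:
        vtx = int([a, b, c][int(np.flatnonzero(~zero)[0])])
        return mesh.vertex_normals[vtx]
    # on an edge: average the normals of the faces sharing it
    idx = [a, b, c]
    pair = [idx[i] for i in np.flatnonzero(~zero)]
    key = (min(pair), max(pair))
    faces = mesh._edge_face_map().get(key, [face_index])
    n = mesh.face_normals[faces].sum(axis=0)
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else mesh.face_normals[face_index]


def signed_distance(p: np.ndarray, mesh: TriMesh) -> float:
    """Signed distance to the surface: positive on the outward-normal side.

    Under the planning convention, positive means the drill tip has not yet
    reached the planned surface (material remains) and negative means it has
    cut past the plan.  The sign at edges and vertices uses the angle-weighted
    pseudonormal, which classifies inside/outside correctly on closed meshes.
    """
    p = np.asarray(p, dtype=float).reshape(3)
    point, dist, face = closest_point_on_mesh(p, mesh)
    n = _pseudonormal_at(mesh, face, point)
    return dist if (p - point) @ n >= 0 else -dist


def signed_distances(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """Vector version of :func:`signed_distance` for a batch of query points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return np.array([signed_distance(q, mesh) for q in pts])


def line_mesh_intersections(
    origin: np.ndarray, direction: np.ndarray, mesh: TriMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect the infinite line ``origin + t * direction`` with every face.

    Möller–Trumbore, vectorised over faces; both directions of the line are
    reported (t may be negative).  Returns (t values in mm, face indices),
    unsorted.  ``direction`` need not be unit length; t is in units of its
    norm, so pass a unit vector to get millimetres.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("line query against an empty mesh")
    o = np.asarray(origin, dtype=float).reshape(3)
    d = np.asarray(direction, dtype=float).reshape(3)
    tri = mesh.triangles
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    eps = 1e-12
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = o - tri[:, 0]
    u = np.einsum("ij,ij->i", pvec, tvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", qvec, d) * inv_det
    t = np.einsum("ij,ij->i", qvec, e2) * inv_det
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps)
    return t[hit], np.flatnonzero(hit)
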