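"""Virtual planning: mirror the healthy hemiface across the midsagittal plane.

Unilateral craniofacial fibrous dysplasia deforms one side of the face while
the contralateral side keeps its normal contour.  The planned post-operative
surface is therefore the mirror image of the healthy side, reflected across
the patient's median sagittal plane; the bone standing proud of that mirrored
surface is the excess to be shaved off.

The pipeline is:

1. :func:`fit_midsagittal_plane` — least-squares symmetry plane from named
   anatomical landmarks (midline points and left/right pairs).
2. :func:`mirror_across_plane` — Householder reflection of the full mesh with
   a winding flip so normals stay outward.
3. :func:`build_plan` — per-vertex excess thickness of the affected side over
   the mirrored surface, thresholded into a resection region.
4. :func:`excess_volume` — the lesion volume the surgeon will remove, a
   quantity that is hard to judge intra-operatively by eye.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    GeometryError,
    Plane,
    TriMesh,
    closest_point_on_mesh,
    signed_distance,
)

__all__ = [
    "LandmarkSet",
    "PlanModel",
    "InsufficientLandmarksError",
    "CollinearLandmarksError",
    "PlaneSeparationError",
    "fit_midsagittal_plane",
    "mirror_across_plane",
    "build_plan",
    "excess_volume",
]

# Resection-region membership: a face is marked for resection when its
# vertices stand outside the mirrored surface by more than this (mm).  Below
# this level, excess is indistinguishable from mirroring/segmentation noise.
DEFAULT_EXCESS_THRESHOLD_MM = 0.5

#: Midline landmark vocabulary (single points on the median plane).  Paired
#: landmarks use a shared stem with an ``_l`` / ``_r`` suffix, e.g.
#: ``zygion_l`` / ``zygion_r``.
MIDLINE_LANDMARKS = ("nasion", "basion", "bregma", "gnathion", "opisthion", "vertex_point")


class InsufficientLandmarksError(GeometryError):
    """Not enough midline points or left/right pairs to fit a plane."""


class CollinearLandmarksError(GeometryError):
    """The landmark configuration leaves the symmetry plane underdetermined."""


class PlaneSeparationError(GeometryError):
    """The supplied plane does not split the mesh into two sides."""


@dataclass
class LandmarkSet:
    """Named anatomical points in mm.

    Midline landmarks are any names without an ``_l``/``_r`` suffix; paired
    landmarks share a stem and differ only in the suffix.  At least three
    midline landmarks or three complete left/right pairs are required for
    symmetry-plane fitting.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    @property
    def midline(self) -> dict[str, np.ndarray]:
        return {
            k: v
            for k, v in self.points.items()
            if not (k.lower().endswith("_l") or k.lower().endswith("_r"))
        }

    @property
    def pairs(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Stem -> (left point, right point) for complete pairs."""
        out = {}
        for k, v in self.points.items():
            if k.lower().endswith("_l"):
                stem = k[:-2]
                right = self.points.get(stem + "_r")
                if right is None:
                    right = self.points.get(stem + "_R")
                if right is not None:
                    out[stem] = (v, right)
        return out

    def validate(self) -> None:
        if len(self.midline) < 3 and len(self.pairs) < 3:
            raise InsufficientLandmarksError(
                "need >= 3 midline landmarks or >= 3 left/right pairs, got "
                f"{len(self.midline)} midline and {len(self.pairs)} pairs"
            )

    # -- I/O: plain {name: [x, y, z]} JSON ----------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        with open(path) as fh:
            return cls({k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in self.points.items()}, fh, indent=1)


@dataclass
class PlanModel:
    """The virtual surgical plan.

    ``planned_surface`` is the mirrored healthy contour restricted to the
    lesion footprint; ``resection_faces`` indexes the faces of the pre-op
    mesh where bone must be removed; ``excess_map`` holds, per pre-op vertex,
    the thickness of bone standing outside the planned surface (0 elsewhere).
    """

    planned_surface: TriMesh
    resection_faces: np.ndarray
    source_plane: Plane
    excess_map: np.ndarray
    preop: TriMesh | None = None
    affected_side: str = "right"
    threshold_mm: float = DEFAULT_EXCESS_THRESHOLD_MM

    def __post_init__(self) -> None:
        self.resection_faces = np.asarray(self.resection_faces, dtype=np.int64)
        self.excess_map = np.asarray(self.excess_map, dtype=float)
        if len(self.excess_map) and self.excess_map.min() < 0:
            raise GeometryError("excess_map must be non-negative")

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            planned_vertices=self.planned_surface.vertices,
            planned_faces=self.planned_surface.faces,
            resection_faces=self.resection_faces,
            plane_point=self.source_plane.point,
            plane_normal=self.source_plane.normal,
            excess_map=self.excess_map,
            preop_vertices=self.preop.vertices if self.preop is not None else np.zeros((0, 3)),
            preop_faces=self.preop.faces if self.preop is not None else np.zeros((0, 3), dtype=int),
            affected_side=np.array(self.affected_side),
            threshold_mm=np.array(self.threshold_mm),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PlanModel":
        z = np.load(path, allow_pickle=False)
        preop = None
        if len(z["preop_vertices"]):
            preop = TriMesh(z["preop_vertices"], z["preop_faces"])
        return cls(
            planned_surface=TriMesh(z["planned_vertices"], z["planned_faces"]),
            resection_faces=z["resection_faces"],
            source_plane=Plane(z["plane_point"], z["plane_normal"]),
            excess_map=z["excess_map"],
            preop=preop,
            affected_side=str(z["affected_side"]),
            threshold_mm=float(z["threshold_mm"]),
        )


# ---------------------------------------------------------------------------
# Symmetry-plane fitting
# ---------------------------------------------------------------------------


def fit_midsagittal_plane(landmarks: LandmarkSet) -> Plane:
    """Least-squares median sagittal plane from midline and paired landmarks.

    Minimises, jointly over the plane (q, n) with unit normal n:

    * squared distances of midline landmarks to the plane,
    * squared distances of each left/right pair's midpoint to the plane,
    * the squared component of each pair axis (right - left) perpendicular
      to the normal (a symmetric pair's axis should be parallel to n).

    With q fixed at the centroid of the on-plane points, the objective is the
    quadratic form nᵀ(C - D)n where C is the scatter of midline points and
    pair midpoints and D the outer-product sum of pair axes; the minimiser is
    the eigenvector of the smallest eigenvalue.  Pairs are thus weighted by
    their squared separation, so widely spaced pairs dominate — desirable,
    since their axis direction is better determined.

    The normal is oriented from the anatomical left toward the right when
    pairs are available; otherwise the sign is fixed so the largest-magnitude
    component of the normal is positive.
    """
    landmarks.validate()
    midline = list(landmarks.midline.values())
    pairs = list(landmarks.pairs.values())

    on_plane = [np.asarray(p) for p in midline] + [(l + r) / 2.0 for l, r in pairs]
    P = np.array(on_plane)
    q = P.mean(axis=0)
    C = (P - q).T @ (P - q)
    D = np.zeros((3, 3))
    for l, r in pairs:
        d = r - l
        D += np.outer(d, d)

    w, v = np.linalg.eigh(C - D)
    scale = max(1.0, float(np.trace(C) + np.trace(D)))
    if (w[1] - w[0]) <= 1e-9 * scale:
        raise CollinearLandmarksError(
            "landmarks are rank-deficient (collinear midline points?); "
            "the symmetry plane is underdetermined"
        )
    n = v[:, 0]

    if pairs:
        axis = np.sum([r - l for l, r in pairs], axis=0)
        if axis @ n < 0:
            n = -n
    elif n[int(np.argmax(np.abs(n)))] < 0:
        n = -n
    return Plane(q, n)


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def mirror_across_plane(mesh: TriMesh, plane: Plane) -> TriMesh:
    """Reflect a mesh across a plane, flipping face winding.

    The reflection p ↦ p - 2((p-q)·n)n is an isometry with determinant -1;
    reversing each face's vertex order restores outward orientation, so the
    signed volume of a closed mesh is preserved rather than negated.
    """
    reflected = plane.reflect(mesh.vertices)
    return TriMesh(
        reflected,
        mesh.faces[:, ::-1].copy(),
        {k: v.copy() for k, v in mesh.face_tags.items()},
        {k: v.copy() for k, v in mesh.vertex_tags.items()},
    )


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------


def _side_sign(affected_side: str) -> float:
    # plane normals are oriented left -> right, so the right side is positive
    side = affected_side.lower()
    if side not in ("left", "right"):
        raise ValueError(f"affected_side must be 'left' or 'right', got {affected_side!r}")
    return 1.0 if side == "right" else -1.0


def build_plan(
    preop: TriMesh,
    plane: Plane,
    affected_side: str = "right",
    threshold_mm: float = DEFAULT_EXCESS_THRESHOLD_MM,
) -> PlanModel:
    """Mirror the healthy side onto the affected side and delimit the resection.

    Per affected-side vertex, the excess thickness is the signed distance from
    the pre-op surface to the mirrored surface (positive = bone outside the
    planned contour), clamped at zero.  Faces whose three vertices all exceed
    ``threshold_mm`` of excess form the resection region; the planned surface
    is the mirrored mesh restricted to the faces overlying that region.
    """
    sign = _side_sign(affected_side)
    side_dist = sign * plane.signed_distance(preop.vertices)
    if side_dist.max() <= 0 or side_dist.min() >= 0:
        raise PlaneSeparationError("plane does not separate the mesh into two sides")

    mirrored = mirror_across_plane(preop, plane)

    excess = np.zeros(len(preop.vertices))
    affected = np.flatnonzero(side_dist > 0)
    for vi in affected:
        excess[vi] = max(0.0, signed_distance(preop.vertices[vi], mirrored))

    face_excess_ok = np.all(excess[preop.faces] > threshold_mm, axis=1)
    face_on_side = np.all(side_dist[preop.faces] > 0, axis=1)
    resection_faces = np.flatnonzero(face_excess_ok & face_on_side)

    # zero the map outside the resection region (clamping contract)
    keep_vertices = np.zeros(len(preop.vertices), dtype=bool)
    if len(resection_faces):
        keep_vertices[np.unique(preop.faces[resection_faces])] = True
    excess = np.where(keep_vertices, excess, 0.0)

    if len(resection_faces) == 0:
        warnings.warn("no excess found: resection region is empty", stacklevel=2)
        planned = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    else:
        resection_set = set(int(f) for f in resection_faces)
        mirrored_centroids = mirrored.triangles.mean(axis=1)
        on_side = sign * plane.signed_distance(mirrored_centroids) > 0
        planned_faces = []
        for fi in np.flatnonzero(on_side):
            _, _, nearest_preop_face = closest_point_on_mesh(mirrored_centroids[fi], preop)
            if nearest_preop_face in resection_set:
                planned_faces.append(fi)
        planned = mirrored.submesh(np.asarray(planned_faces, dtype=np.int64))

    preop_tagged = TriMesh(
        preop.vertices.copy(),
        preop.faces.copy(),
        {**{k: v.copy() for k, v in preop.face_tags.items()}, "surgical_area": resection_faces},
    )
    return PlanModel(
        planned_surface=planned,
        resection_faces=resection_faces,
        source_plane=plane,
        excess_map=excess,
        preop=preop_tagged,
        affected_side=affected_side,
        threshold_mm=threshold_mm,
    )


def excess_volume(plan: PlanModel) -> float:
    """Volume of bone to remove, in mm³.

    Integrates the per-vertex excess thickness against barycentric-lumped
    vertex areas of the pre-op surface (a prism summation).  An empty
    resection region integrates to zero.
    """
    if plan.preop is None:
        raise GeometryError("excess_volume requires the plan to carry its pre-op mesh")
    if len(plan.resection_faces) == 0:
        return 0.0
    va = plan.preop.vertex_areas
    return float(np.sum(plan.excess_map * va))
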