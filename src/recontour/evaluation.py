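"""Post-operative accuracy evaluation against the virtual plan.

The accuracy of a recontouring procedure is judged by superimposing the
post-operative CT surface onto the planned (mirrored) surface:

1. :func:`align_postop` — rigid alignment using paired points picked on the
   *unchanged* region of the skull (bone the surgery did not touch), with
   optional ICP refinement restricted to that region.
2. :func:`sample_paired_points` — hundreds of source points drawn
   area-uniformly on the planned surface within the surgical area, each
   paired with the nearest intersection of the post-op surface along the
   planned surface's normal (both directions searched).
3. :func:`deviation_stats` — min / max / mean ± SD of the paired-point
   separations: one case's row of the error table.
4. :func:`aggregate_cases` — grand mean and SD across cases.

SD is the population standard deviation (divide by n) throughout: applied to
per-case means of 1.277, 1.218, 1.525, 1.861 and 1.326 mm it reproduces a
cross-case spread of 0.234 mm, whereas the sample convention gives 0.261.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    GeometryError,
    RigidTransform,
    TriMesh,
    closest_point_on_mesh,
    line_mesh_intersections,
)
from .registration import CorrespondenceSet, icp_refine, paired_point_register

__all__ = [
    "DeviationReport",
    "AggregateReport",
    "align_postop",
    "sample_paired_points",
    "deviation_stats",
    "aggregate_cases",
    "export_deviation_heatmap",
]

# Normal rays that miss the post-op surface within this distance indicate a
# correspondence failure (hole, boundary), not a surgical deviation.
NORMAL_RAY_CUTOFF_MM = 10.0


@dataclass
class DeviationReport:
    """Per-case paired-point deviation summary (the error-table row).

    All statistics are recomputed from the stored per-point distances;
    ``sd`` is the population standard deviation.
    """

    case_id: str
    distances_mm: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float).reshape(-1)
        if len(self.distances_mm) == 0:
            raise GeometryError("deviation report needs at least one pair")

    @property
    def n_points(self) -> int:
        return len(self.distances_mm)

    @property
    def min_mm(self) -> float:
        return float(np.min(self.distances_mm))

    @property
    def max_mm(self) -> float:
        return float(np.max(self.distances_mm))

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.distances_mm))

    @property
    def sd_mm(self) -> float:
        return float(np.std(self.distances_mm))  # population SD

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "n_points": self.n_points,
            "n_discarded": self.n_discarded,
            "min_mm": self.min_mm,
            "max_mm": self.max_mm,
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def distances_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pair_index", "distance_mm"])
            for i, d in enumerate(self.distances_mm):
                w.writerow([i, f"{d:.6f}"])


@dataclass
class AggregateReport:
    """Cross-case aggregation: grand mean and population SD of per-case means."""

    per_case_means_mm: np.ndarray
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_case_means_mm = np.asarray(self.per_case_means_mm, dtype=float).reshape(-1)
        if len(self.per_case_means_mm) == 0:
            raise GeometryError("aggregate needs at least one case")

    @property
    def grand_mean_mm(self) -> float:
        return float(np.mean(self.per_case_means_mm))

    @property
    def grand_sd_mm(self) -> float:
        return float(np.std(self.per_case_means_mm))  # population SD

    def to_dict(self) -> dict:
        return {
            "case_ids": self.case_ids or [str(i + 1) for i in range(len(self.per_case_means_mm))],
            "per_case_means_mm": [float(x) for x in self.per_case_means_mm],
            "grand_mean_mm": self.grand_mean_mm,
            "grand_sd_mm": self.grand_sd_mm,
        }


def align_postop(
    postop: TriMesh,
    plan_context: TriMesh,
    unchanged_corr: CorrespondenceSet,
    refine: bool = False,
    n_icp_points: int = 200,
    seed: int = 0,
) -> RigidTransform:
    """Rigidly map plan space into post-op space via unchanged-region pairs.

    ``unchanged_corr`` pairs points in plan space (on ``plan_context``) with
    their counterparts on the post-op surface; these must lie on bone the
    surgery left untouched, and a warning is emitted when any source point
    sits on a face tagged ``surgical_area``.  With ``refine=True``, points
    sampled from the unchanged region of the plan-context mesh are ICP-fitted
    to the post-op surface starting from the paired-point solution.
    """
    if "surgical_area" in plan_context.face_tags and len(plan_context.face_tags["surgical_area"]):
        surgical = set(int(f) for f in plan_context.face_tags["surgical_area"])
        for p in unchanged_corr.source:
            _, _, face = closest_point_on_mesh(p, plan_context)
            if face in surgical:
                warnings.warn(
                    "a correspondence point lies on the surgical area; "
                    "alignment should use unchanged bone only",
                    stacklevel=2,
                )
                break

    transform, _ = paired_point_register(unchanged_corr, "plan", "postop")
    if not refine:
        return transform

    if "unchanged" in plan_context.face_tags and len(plan_context.face_tags["unchanged"]):
        region = plan_context.submesh(plan_context.face_tags["unchanged"])
    elif "surgical_area" in plan_context.face_tags:
        keep = np.setdiff1d(
            np.arange(plan_context.n_faces), plan_context.face_tags["surgical_area"]
        )
        region = plan_context.submesh(keep)
    else:
        region = plan_context
    rng = np.random.default_rng(seed)
    pts, _ = _area_uniform_sample(region, np.arange(region.n_faces), n_icp_points, rng)
    refined, _, _ = icp_refine(pts, postop, transform)
    return refined


def _area_uniform_sample(
    mesh: TriMesh, face_indices: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n points area-uniformly on the given faces (faces chosen with
    probability proportional to area, positions uniform by the square-root
    barycentric trick).  Returns (points, face index per point)."""
    areas = mesh.face_areas[face_indices]
    total = areas.sum()
    if total <= 0:
        raise GeometryError("sampling region has zero area")
    chosen = rng.choice(len(face_indices), size=n, p=areas / total)
    faces = face_indices[chosen]
    tri = mesh.triangles[faces]
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    pts = a[:, None] * tri[:, 0] + b[:, None] * tri[:, 1] + c[:, None] * tri[:, 2]
    return pts, faces


def sample_paired_points(
    planned: TriMesh,
    postop: TriMesh,
    region: np.ndarray | None = None,
    n: int = 500,
    seed: int = 0,
    cutoff_mm: float = NORMAL_RAY_CUTOFF_MM,
) -> CorrespondenceSet:
    """Generate paired points between the planned and post-op surfaces.

    Source points are sampled area-uniformly on the planned surface within
    ``region`` (face indices; the whole surface when None).  Each source
    point is paired with the nearest intersection of the post-op mesh along
    the planned surface's normal at that point, searching both directions.
    Pairs with no intersection within ``cutoff_mm`` are discarded and
    counted; a warning is raised when more than 20% are discarded.
    """
    if region is None:
        region = np.arange(planned.n_faces)
    region = np.asarray(region, dtype=np.int64)
    if len(region) == 0:
        raise GeometryError("paired-point sampling region is empty")
    if n < 1:
        raise GeometryError("need n >= 1 sample points")
    rng = np.random.default_rng(seed)
    sources, faces = _area_uniform_sample(planned, region, n, rng)
    normals = planned.face_normals[faces]

    kept_src, kept_tgt = [], []
    n_discarded = 0
    for p, nvec in zip(sources, normals):
        ts, _ = line_mesh_intersections(p, nvec, postop)
        ts = ts[np.abs(ts) <= cutoff_mm]
        if len(ts) == 0:
            n_discarded += 1
            continue
        t_near = ts[np.argmin(np.abs(ts))]
        kept_src.append(p)
        kept_tgt.append(p + t_near * nvec)
    if n_discarded > 0.2 * n:
        warnings.warn(
            f"{n_discarded}/{n} normal rays missed the post-op surface within "
            f"{cutoff_mm} mm",
            stacklevel=2,
        )
    if not kept_src:
        raise GeometryError("no paired points found within the cutoff")
    corr = CorrespondenceSet(np.array(kept_src), np.array(kept_tgt))
    corr.n_discarded = n_discarded  # type: ignore[attr-defined]
    return corr


def deviation_stats(pairs: CorrespondenceSet, case_id: str = "case") -> DeviationReport:
    """Summarise paired-point separations into a deviation report.

    Distances are unsigned Euclidean separations (the error table's minima
    are near zero, not negative).
    """
    return DeviationReport(
        case_id=case_id,
        distances_mm=pairs.distances,
        n_discarded=int(getattr(pairs, "n_discarded", 0)),
    )


def aggregate_cases(per_case_means_mm, case_ids: list[str] | None = None) -> AggregateReport:
    """Grand mean ± population SD of the per-case mean deviations."""
    return AggregateReport(np.asarray(per_case_means_mm, dtype=float), case_ids or [])


def export_deviation_heatmap(
    mesh: TriMesh, vertex_values_mm: np.ndarray, path: str | Path, vmax_mm: float | None = None
) -> None:
    """Write a PLY of ``mesh`` with per-vertex colours encoding deviation
    (blue = 0 through red = ``vmax_mm``), for inspection in any mesh viewer."""
    vals = np.asarray(vertex_values_mm, dtype=float).reshape(-1)
    if len(vals) != len(mesh.vertices):
        raise GeometryError("one value per vertex required")
    vmax = vmax_mm if vmax_mm is not None else max(float(vals.max()), 1e-12)
    t = np.clip(vals / vmax, 0.0, 1.0)
    colors = np.stack(
        [
            (255 * t).astype(np.uint8),
            np.zeros(len(t), dtype=np.uint8),
            (255 * (1.0 - t)).astype(np.uint8),
            np.full(len(t), 255, dtype=np.uint8),
        ],
        axis=1,
    )
    tm = mesh.to_trimesh()
    tm.visual.vertex_colors = colors
    tm.export(str(path))
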