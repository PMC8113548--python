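"""Rigid registration and the tracked coordinate-frame graph.

The navigation setup links four frames: the optical TRACKER, a reference
array screwed to the patient (PATIENT_DRF), another clamped to the surgical
drill (DRILL_DRF), and the CT-derived IMAGE space holding the meshes and the
plan.  Static edges (e.g. the patient-to-image registration) are measured
once; tracked edges (tracker-to-DRF poses) arrive as time-stamped streams
and are interpolated — translation linearly, rotation by spherical-linear
interpolation on unit quaternions.

Paired-point registration is the closed-form Kabsch/Umeyama SVD solution
with the determinant corrected so reflections are never returned; its
residual RMS is the fiducial registration error (FRE).  ICP alternates
closest-point correspondence against a target surface with that same
closed-form fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .geometry import (
    GeometryError,
    RigidTransform,
    TriMesh,
    closest_points_on_mesh,
    compose,
    invert,
)

__all__ = [
    "TRACKER",
    "PATIENT_DRF",
    "DRILL_DRF",
    "IMAGE",
    "CorrespondenceSet",
    "TipCalibration",
    "PoseTrack",
    "PoseStream",
    "FrameGraph",
    "DegenerateConfigurationError",
    "DisconnectedFramesError",
    "TimestampRangeError",
    "paired_point_register",
    "icp_refine",
    "drill_tip_in_image",
]

# Canonical frame names of the navigation setup.
TRACKER = "TRACKER"
PATIENT_DRF = "PATIENT_DRF"
DRILL_DRF = "DRILL_DRF"
IMAGE = "IMAGE"

# ICP correspondence rejection: pairs farther than this multiple of the
# median pair distance are dropped each iteration (robustness to partial
# overlap between the post-op scan and the planned surface).
ICP_REJECT_MEDIAN_FACTOR = 5.0


class DegenerateConfigurationError(GeometryError):
    """Point configuration does not determine a unique rigid transform."""


class DisconnectedFramesError(GeometryError):
    """No path between the requested frames in the frame graph."""


class TimestampRangeError(GeometryError):
    """Requested time lies outside a tracked edge's sample range."""


@dataclass
class CorrespondenceSet:
    """Ordered paired points (source[i] corresponds to target[i]), in mm.

    Registration requires at least three non-collinear pairs; smaller sets
    are permitted in the container so that deviation reports can be built
    from arbitrary pair counts.
    """

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if len(self.source) != len(self.target):
            raise GeometryError("source and target must have equal length")
        if len(self.source) == 0:
            raise GeometryError("correspondence set is empty")

    def __len__(self) -> int:
        return len(self.source)

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.target - self.source, axis=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrespondenceSet":
        """Read a JSON array of [[sx,sy,sz],[tx,ty,tz]] pairs."""
        with open(path) as fh:
            pairs = json.load(fh)
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    def to_json(self, path: str | Path) -> None:
        pairs = [[list(map(float, s)), list(map(float, t))] for s, t in zip(self.source, self.target)]
        with open(path, "w") as fh:
            json.dump(pairs, fh)


@dataclass(frozen=True)
class TipCalibration:
    """Fixed drill-tip offset in the DRILL_DRF frame, mm (from pivot calibration)."""

    offset: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.offset, dtype=float).reshape(3)
        if not np.all(np.isfinite(o)) or np.linalg.norm(o) >= 500.0:
            raise GeometryError("tip offset must be finite and < 500 mm")
        object.__setattr__(self, "offset", o)

    @classmethod
    def from_json(cls, path: str | Path) -> "TipCalibration":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["offset_mm"], dtype=float))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"offset_mm": list(map(float, self.offset))}, fh)


# ---------------------------------------------------------------------------
# Paired-point (Kabsch) registration
# ---------------------------------------------------------------------------


def paired_point_register(
    corr: CorrespondenceSet,
    source_frame: str = "source",
    target_frame: str = "target",
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of source onto target points.

    Closed-form SVD (Kabsch) solution; if the optimal orthogonal matrix is a
    reflection, the singular direction with the smallest singular value is
    flipped to give the best proper rotation.  Returns the transform and the
    FRE, defined as the root-mean-square residual of the transformed source
    against the target.

    Raises :class:`DegenerateConfigurationError` for fewer than three pairs,
    duplicated source points, or (near-)collinear source configurations.
    """
    if len(corr) < 3:
        raise DegenerateConfigurationError("paired-point registration needs >= 3 pairs")
    src, tgt = corr.source, corr.target
    if len(np.unique(np.round(src, 9), axis=0)) < len(src):
        raise DegenerateConfigurationError("duplicated source points")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # collinearity: the centred source must span at least a 2-D subspace
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(1.0, sv[0]):
        raise DegenerateConfigurationError("source points are collinear")

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    transform = RigidTransform(R, t, source_frame, target_frame)

    residuals = transform.apply(src) - tgt
    fre = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, fre


def icp_refine(
    source_points: np.ndarray,
    target: TriMesh,
    init: RigidTransform,
    max_iter: int = 2000,
    tol_mm: float = 1e-12,
) -> tuple[RigidTransform, float, dict]:
    """Iterative closest point: refine ``init`` so the points fit the surface.

    Each iteration finds closest points on the target mesh, rejects pairs
    farther than ``ICP_REJECT_MEDIAN_FACTOR`` times the median distance, and
    solves the closed-form rigid fit on the survivors.  Stops when the RMS
    improves by less than ``tol_mm`` or after ``max_iter`` iterations (the
    latter sets ``info["converged"] = False`` — flagged, not fatal).

    Point-to-point ICP corrects tangential misalignment slowly on smooth,
    low-curvature surfaces (correspondences slide along the surface), hence
    the generous default iteration budget; runs that start near the optimum
    stop after a handful of iterations via the tolerance.

    Returns (refined transform, final RMS in mm, info dict with the
    per-iteration ``rms_history`` and convergence flag).
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    if len(src) == 0:
        raise GeometryError("ICP needs a non-empty source point set")
    src = np.unique(src, axis=0)  # duplicate samples add nothing to the fit
    current = init
    rms_history: list[float] = []
    converged = False
    for _ in range(max_iter):
        moved = current.apply(src)
        closest, dists, _ = closest_points_on_mesh(moved, target)
        keep = dists <= ICP_REJECT_MEDIAN_FACTOR * max(np.median(dists), 1e-300)
        if keep.sum() < 3:
            keep = np.ones(len(moved), dtype=bool)
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        if rms_history and rms_history[-1] - rms < tol_mm:
            rms_history.append(rms)
            converged = True
            break
        rms_history.append(rms)
        step, _ = paired_point_register(
            CorrespondenceSet(moved[keep], closest[keep]),
            source_frame=current.target_frame,
            target_frame=current.target_frame,
        )
        current = compose(current, step)
    return current, rms_history[-1], {"rms_history": rms_history, "converged": converged}


# ---------------------------------------------------------------------------
# Tracked poses and the frame graph
# ---------------------------------------------------------------------------


@dataclass
class PoseTrack:
    """A time-stamped sequence of rigid poses for one tracked edge.

    Sampling between timestamps interpolates translation linearly and
    rotation by Slerp; sampling outside the recorded range raises
    :class:`TimestampRangeError`.
    """

    times: np.ndarray
    transforms: list[RigidTransform]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if len(self.times) != len(self.transforms):
            raise GeometryError("times and transforms must have equal length")
        if len(self.times) == 0:
            raise GeometryError("empty pose track")
        if np.any(np.diff(self.times) <= 0):
            raise GeometryError("pose track timestamps must be strictly increasing")
        frames = {(t.source_frame, t.target_frame) for t in self.transforms}
        if len(frames) != 1:
            raise GeometryError("all poses in a track must share the same frames")
        self.source_frame, self.target_frame = next(iter(frames))

    def sample(self, at: float) -> RigidTransform:
        if at < self.times[0] or at > self.times[-1]:
            raise TimestampRangeError(
                f"time {at} outside tracked range [{self.times[0]}, {self.times[-1]}]"
            )
        j = int(np.searchsorted(self.times, at))
        if j < len(self.times) and self.times[j] == at:
            return self.transforms[j]
        t0, t1 = self.times[j - 1], self.times[j]
        w = (at - t0) / (t1 - t0)
        a, b = self.transforms[j - 1], self.transforms[j]
        trans = (1 - w) * a.translation + w * b.translation
        rots = Rotation.from_matrix(np.stack([a.rotation, b.rotation]))
        rot = Slerp([0.0, 1.0], rots)(w).as_matrix()
        return RigidTransform(rot, trans, a.source_frame, a.target_frame)


@dataclass
class PoseStream:
    """Per-frame pose tracks, each expressing FRAME -> TRACKER motion."""

    tracks: dict[str, PoseTrack] = field(default_factory=dict)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PoseStream":
        """Load the pose-stream dialect: columns
        time_s, frame, qw, qx, qy, qz, tx, ty, tz (translations in mm)."""
        df = pd.read_csv(path)
        tracks = {}
        for frame, grp in df.groupby("frame"):
            grp = grp.sort_values("time_s")
            tfs = [
                RigidTransform.from_quat(
                    row[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
                    row[["tx", "ty", "tz"]].to_numpy(dtype=float),
                    source_frame=str(frame),
                    target_frame=TRACKER,
                )
                for _, row in grp.iterrows()
            ]
            tracks[str(frame)] = PoseTrack(grp["time_s"].to_numpy(dtype=float), tfs)
        return cls(tracks)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for frame, track in self.tracks.items():
            for t, tf in zip(track.times, track.transforms):
                w, x, y, z = tf.to_quat()
                tx, ty, tz = tf.translation
                rows.append(
                    {"time_s": t, "frame": frame, "qw": w, "qx": x, "qy": y, "qz": z,
                     "tx": tx, "ty": ty, "tz": tz}
                )
        pd.DataFrame(rows).to_csv(path, index=False)


class FrameGraph:
    """Named coordinate frames joined by static or tracked rigid edges.

    Edges are stored directed (source -> target) but traversed both ways;
    :meth:`resolve` composes the transforms along the unique BFS path.
    """

    def __init__(self) -> None:
        self.frames: set[str] = set()
        self._static: dict[tuple[str, str], RigidTransform] = {}
        self._tracked: dict[tuple[str, str], PoseTrack] = {}

    def add_static_edge(self, t: RigidTransform) -> None:
        self.frames.update((t.source_frame, t.target_frame))
        self._static[(t.source_frame, t.target_frame)] = t

    def add_tracked_edge(self, track: PoseTrack) -> None:
        self.frames.update((track.source_frame, track.target_frame))
        self._tracked[(track.source_frame, track.target_frame)] = track

    def add_stream(self, stream: PoseStream) -> None:
        for track in stream.tracks.values():
            self.add_tracked_edge(track)

    def _neighbors(self, frame: str):
        for (a, b) in list(self._static) + list(self._tracked):
            if a == frame:
                yield b, (a, b), False
            elif b == frame:
                yield a, (a, b), True

    def _edge_transform(self, key: tuple[str, str], reverse: bool, at: float | None) -> RigidTransform:
        if key in self._static:
            t = self._static[key]
        else:
            if at is None:
                raise TimestampRangeError(f"tracked edge {key} requires a timestamp")
            t = self._tracked[key].sample(at)
        return invert(t) if reverse else t

    def resolve(self, a: str, b: str, at: float | None = None) -> RigidTransform:
        """Rigid transform mapping frame ``a`` into frame ``b`` (at time ``at``
        if tracked edges lie on the path)."""
        if a not in self.frames or b not in self.frames:
            raise DisconnectedFramesError(f"unknown frame in resolve({a!r}, {b!r})")
        if a == b:
            return RigidTransform.identity(a)
        # BFS for the shortest path a -> b
        prev: dict[str, tuple[str, tuple[str, str], bool]] = {}
        queue = [a]
        seen = {a}
        while queue:
            cur = queue.pop(0)
            if cur == b:
                break
            for nxt, key, reverse in self._neighbors(cur):
                if nxt not in seen:
                    seen.add(nxt)
                    prev[nxt] = (cur, key, reverse)
                    queue.append(nxt)
        if b not in seen:
            raise DisconnectedFramesError(f"frames {a!r} and {b!r} are not connected")
        # reconstruct and compose
        steps = []
        cur = b
        while cur != a:
            parent, key, reverse = prev[cur]
            steps.append((key, reverse))
            cur = parent
        out = RigidTransform.identity(a)
        for key, reverse in reversed(steps):
            out = compose(out, self._edge_transform(key, reverse, at))
        return out

    def check_cycles(self, at: float | None = None, tol: float = 1e-6) -> bool:
        """True when composing every fundamental cycle yields the identity
        within ``tol`` (rotation entries and translation mm).

        Each edge is compared against the path that remains when the edge
        itself is removed; edges whose removal disconnects their endpoints
        close no cycle and are skipped.
        """
        edges = list(self._static) + list(self._tracked)
        for (a, b) in edges:
            direct = self._edge_transform((a, b), False, at)
            removed_static = self._static.pop((a, b), None)
            removed_tracked = None
            if removed_static is None:
                removed_tracked = self._tracked.pop((a, b), None)
            try:
                try:
                    path = self.resolve(a, b, at)
                except DisconnectedFramesError:
                    continue  # tree edge: no cycle through it
                except TimestampRangeError:
                    return False
            finally:
                if removed_static is not None:
                    self._static[(a, b)] = removed_static
                if removed_tracked is not None:
                    self._tracked[(a, b)] = removed_tracked
            delta = compose(invert(path), direct)
            if np.abs(delta.rotation - np.eye(3)).max() > tol:
                return False
            if np.abs(delta.translation).max() > tol:
                return False
        return True


def drill_tip_in_image(frames: FrameGraph, tip: TipCalibration, at: float) -> np.ndarray:
    """Drill-tip position in IMAGE space at time ``at``.

    Maps the calibrated tip offset through the DRILL_DRF -> TRACKER ->
    PATIENT_DRF -> IMAGE chain resolved from the frame graph.
    """
    t = frames.resolve(DRILL_DRF, IMAGE, at)
    return t.apply(tip.offset)
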