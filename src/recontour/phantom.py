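"""Synthetic skull phantoms with ground truth for every pipeline stage.

Patient CT surfaces cannot ship with the package, so every stage is
exercised on a parametric stand-in: a bilaterally symmetric ellipsoid
"skull" with a unilateral Gaussian lesion bump of known height and
footprint.  The ellipsoid-with-bump choice (rather than an anatomical mesh)
keeps the repository download-free and makes analytic oracles possible —
the symmetry plane, the lesion labels, the bump height, the deformation
field and every frame transform are known exactly.

Axis convention: +x is the anatomical right, +y anterior, +z superior, so
the ground-truth midsagittal plane is x = 0 with normal (1, 0, 0) (oriented
left → right, matching the planner's convention).

:func:`simulate_procedure` then fabricates the intra- and post-operative
record: a post-op mesh equal to the planned surface plus a smooth residual
error field of prescribed mean and spread (the magnitude of real shaving
error), scripted drill passes as a tracked pose stream, and the exact
frame transforms — so registration, guidance and evaluation can all be
checked against known truth, with optional pose and fiducial noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh
from scipy.spatial.transform import Rotation

from .geometry import (
    GeometryError,
    Plane,
    RigidTransform,
    TriMesh,
    closest_point_on_mesh,
    compose,
    invert,
)
from .planning import LandmarkSet, PlanModel
from .registration import (
    DRILL_DRF,
    IMAGE,
    PATIENT_DRF,
    TRACKER,
    PoseStream,
    PoseTrack,
    TipCalibration,
)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "NoiseParams",
    "SimulatedProcedure",
    "ResolutionError",
    "make_phantom",
    "simulate_procedure",
    "add_pose_noise",
]

# Vertices displaced by more than this (mm) carry the ground-truth lesion
# label; it matches the planner's default resection threshold, below which
# excess is indistinguishable from mirroring noise.
LESION_LABEL_THRESHOLD_MM = 0.5
# Faces displaced by less than this are the "unchanged" region used for
# post-op alignment.
UNCHANGED_THRESHOLD_MM = 0.05


class ResolutionError(GeometryError):
    """Mesh resolution too coarse for a usable phantom."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the ellipsoid-with-bump phantom.

    ``semi_axes_mm`` are the lateral / anteroposterior / vertical half-widths
    of the skull-scale ellipsoid; the lesion is a Gaussian bump of
    ``lesion_height_mm`` at its centre decaying with length scale
    ``lesion_footprint_mm`` (displacement = h · exp(-(d / w)²) at ambient
    distance d from the bump centre).
    """

    semi_axes_mm: tuple[float, float, float] = (60.0, 85.0, 75.0)
    subdivisions: int = 4
    lesion_side: str = "right"
    lesion_center_dir: tuple[float, float, float] = (1.0, 0.35, 0.25)
    lesion_height_mm: float = 6.0
    lesion_footprint_mm: float = 18.0
    n_fiducials: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_height_mm < 0 or self.lesion_footprint_mm <= 0:
            raise GeometryError("lesion height must be >= 0 and footprint > 0")
        if 20 * 4**self.subdivisions < 1000:
            raise ResolutionError(
                f"subdivisions={self.subdivisions} gives {20 * 4**self.subdivisions} "
                "faces; at least 1,000 required"
            )


@dataclass
class PhantomCase:
    """A generated phantom with its exact ground truth."""

    spec: PhantomSpec
    mesh: TriMesh
    landmarks: LandmarkSet
    fiducials: dict[str, np.ndarray]
    true_plane: Plane
    vertex_displacement_mm: np.ndarray
    lesion_faces: np.ndarray
    unchanged_faces: np.ndarray


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise magnitudes of the tracked setup (all zero = ideal)."""

    pose_trans_sd_mm: float = 0.2
    pose_rot_sd_deg: float = 0.1
    fiducial_sd_mm: float = 0.3


@dataclass
class SimulatedProcedure:
    """A scripted recontouring run with complete ground truth."""

    case: PhantomCase
    plan: PlanModel
    postop: TriMesh
    residual_values_mm: np.ndarray  # per resection-region vertex
    residual_mean_mm: float
    residual_sd_mm: float
    stream: PoseStream  # noise-free tracked poses
    noisy_stream: PoseStream | None
    tip: TipCalibration
    times_s: np.ndarray
    tip_truth_image: np.ndarray  # (n, 3) scripted tip positions, IMAGE frame
    t_patient_image: RigidTransform  # ground-truth registration
    t_patient_tracker: RigidTransform  # static patient DRF pose
    fiducials_image: np.ndarray
    fiducials_patient: np.ndarray  # exact fiducials in the PATIENT_DRF frame
    fiducials_patient_noisy: np.ndarray
    noise: NoiseParams
    seed: int


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def _ellipsoid_point(direction: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Surface point of the ellipsoid along a direction from the origin."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = 1.0 / np.sqrt(np.sum((d / axes) ** 2))
    return t * d


def _ellipsoid_normals(points: np.ndarray, axes: np.ndarray) -> np.ndarray:
    n = points / axes**2
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


_MIDLINE_DIRS = {
    "nasion": (0.0, 1.0, 0.15),
    "bregma": (0.0, 0.15, 1.0),
    "basion": (0.0, -0.5, -1.0),
    "gnathion": (0.0, 1.0, -0.9),
}
_PAIR_DIRS = {
    "porion": (1.0, -0.7, 0.0),
    "orbitale": (0.8, 0.6, 0.6),
    "gonion": (0.8, -0.3, -0.8),
}
_FIDUCIAL_DIRS = [
    (-1.0, 0.2, 0.3),
    (-0.8, -0.6, 0.4),
    (-0.5, 0.7, -0.5),
    (0.0, -1.0, 0.2),
    (0.0, 0.3, 1.0),
    (-0.9, 0.1, -0.6),
    (-0.3, 0.9, 0.5),
    (-0.6, -0.2, 0.9),
]


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomCase:
    """Build the phantom: symmetric ellipsoid plus a one-sided lesion bump.

    The mesh is a subdivided icosphere scaled to the ellipsoid (closed,
    outward-oriented, geometrically mirror-symmetric about x = 0 before the
    bump).  The bump displaces vertices outward along the exact ellipsoid
    normal by h · exp(-(d / w)²).  Landmarks and fiducials are exact points
    of the *ideal* symmetric ellipsoid, placed away from the lesion.
    Construction is deterministic: the same spec yields byte-identical
    output.
    """
    axes = np.asarray(spec.semi_axes_mm, dtype=float)
    sphere = _trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    vertices = np.asarray(sphere.vertices) * axes
    faces = np.asarray(sphere.faces)

    side_sign = 1.0 if spec.lesion_side == "right" else -1.0
    center_dir = np.asarray(spec.lesion_center_dir, dtype=float).copy()
    center_dir[0] = side_sign * abs(center_dir[0])  # bump on the affected side
    bump_center = _ellipsoid_point(center_dir, axes)

    d = np.linalg.norm(vertices - bump_center, axis=1)
    displacement = spec.lesion_height_mm * np.exp(-((d / spec.lesion_footprint_mm) ** 2))
    normals = _ellipsoid_normals(vertices, axes)
    deformed = vertices + displacement[:, None] * normals

    lesion_vertices = displacement > LESION_LABEL_THRESHOLD_MM
    lesion_faces = np.flatnonzero(np.all(lesion_vertices[faces], axis=1))
    unchanged_faces = np.flatnonzero(
        np.all(displacement[faces] < UNCHANGED_THRESHOLD_MM, axis=1)
    )

    mesh = TriMesh(
        deformed,
        faces,
        face_tags={"lesion": lesion_faces, "unchanged": unchanged_faces},
        vertex_tags={"lesion": np.flatnonzero(lesion_vertices)},
    )
    if mesh.signed_volume <= 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.face_tags, mesh.vertex_tags)

    points = {}
    for name, dvec in _MIDLINE_DIRS.items():
        points[name] = _ellipsoid_point(np.asarray(dvec), axes)
    for stem, dvec in _PAIR_DIRS.items():
        dvec = np.asarray(dvec)
        points[stem + "_r"] = _ellipsoid_point(dvec, axes)
        points[stem + "_l"] = _ellipsoid_point(dvec * np.array([-1.0, 1.0, 1.0]), axes)

    fiducials = {
        f"fid_{i}": _ellipsoid_point(np.asarray(dvec), axes)
        for i, dvec in enumerate(_FIDUCIAL_DIRS[: max(3, spec.n_fiducials)])
    }

    return PhantomCase(
        spec=spec,
        mesh=mesh,
        landmarks=LandmarkSet(points),
        fiducials=fiducials,
        true_plane=Plane(np.zeros(3), np.array([1.0, 0.0, 0.0])),
        vertex_displacement_mm=displacement,
        lesion_faces=lesion_faces,
        unchanged_faces=unchanged_faces,
    )


# ---------------------------------------------------------------------------
# Procedure simulation
# ---------------------------------------------------------------------------


def _random_rigid(rng: np.random.Generator, trans_scale_mm: float,
                  source: str, target: str) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0.0, trans_scale_mm, 3)
    return RigidTransform(R, t, source, target)


def _smooth_field(points: np.ndarray, rng: np.random.Generator, n_waves: int = 6) -> np.ndarray:
    """Smooth seeded random field: a low-frequency random Fourier sum, giving
    spatially coherent values like real shaving error (not white noise)."""
    vals = np.zeros(len(points))
    for _ in range(n_waves):
        freq = rng.uniform(1.0 / 80.0, 1.0 / 25.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        vals += rng.normal(0, 1) * np.cos(2 * np.pi * freq * points @ direction + phase)
    return vals


def _scripted_tip_path(plan: PlanModel, times: np.ndarray) -> np.ndarray:
    """Shaving passes over the planned surface: a sweep across the region with
    the stand-off height ramping from 12 mm down to 0.5 mm."""
    surf = plan.planned_surface
    center = surf.vertices.mean(axis=0)
    _, _, face = closest_point_on_mesh(center, surf)
    n = surf.face_normals[face]
    extent = surf.vertices - center
    u = extent[np.argmax(np.linalg.norm(extent, axis=1))]
    u = u - (u @ n) * n
    u /= max(np.linalg.norm(u), 1e-12)
    s = (times - times[0]) / max(times[-1] - times[0], 1e-12)
    height = 12.0 - 11.5 * s
    sweep = 0.6 * np.linalg.norm(extent, axis=1).max() * np.sin(2 * np.pi * 3 * s)
    return center + height[:, None] * n + sweep[:, None] * u


def simulate_procedure(
    case: PhantomCase,
    plan: PlanModel,
    residual_mean_mm: float = 1.4,
    residual_sd_mm: float = 0.7,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    n_poses: int = 240,
    duration_s: float = 60.0,
) -> SimulatedProcedure:
    """Fabricate the full surgical record of one phantom case.

    The post-op mesh moves every resection-region vertex onto its closest
    point of the planned surface, then offsets it outward along the planned
    surface normal by a smooth residual field standardised to exactly the
    requested mean and SD over the region vertices — the ground-truth
    "surgical discrepancy" the evaluation pipeline should recover.  The
    defaults (1.4 ± 0.7 mm) sit at the magnitude of reported recontouring
    errors.  The drill pose stream scripts shaving passes whose noise-free
    replay reproduces the scripted tip path exactly; all randomness derives
    from the single ``seed``.
    """
    rng = np.random.default_rng(seed)

    # --- post-op mesh -------------------------------------------------------
    # Region vertices land on the planned (mirrored) surface plus the
    # residual.  A two-ring collar of surrounding vertices is deformed onto
    # the mirrored surface the same way: without it, boundary faces would
    # interpolate between shaved and untouched bone and bias paired-point
    # distances sampled near the rim low.
    postop_vertices = case.mesh.vertices.copy()
    region_vertices = (
        np.unique(case.mesh.faces[plan.resection_faces])
        if len(plan.resection_faces)
        else np.array([], dtype=np.int64)
    )
    residuals = np.zeros(len(region_vertices))
    if len(region_vertices):
        from .planning import mirror_across_plane

        mirrored = mirror_across_plane(case.mesh, plan.source_plane)
        in_set = set(region_vertices.tolist())
        moved = np.array(sorted(in_set), dtype=np.int64)
        for _ in range(2):
            touch = np.any(np.isin(case.mesh.faces, moved), axis=1)
            moved = np.unique(case.mesh.faces[touch])
        raw_all = _smooth_field(case.mesh.vertices[moved], rng)
        pos = {int(v): k for k, v in enumerate(moved)}
        raw_region = raw_all[[pos[int(v)] for v in region_vertices]]
        mu_raw, sd_raw = raw_region.mean(), raw_region.std()
        if residual_sd_mm > 0 and sd_raw > 0:
            field_all = residual_mean_mm + residual_sd_mm * (raw_all - mu_raw) / sd_raw
        else:
            field_all = np.full(len(moved), residual_mean_mm)
        residuals = field_all[[pos[int(v)] for v in region_vertices]]
        for k, vi in enumerate(moved):
            target, _, face = closest_point_on_mesh(case.mesh.vertices[vi], mirrored)
            n = mirrored.face_normals[face]
            postop_vertices[vi] = target + field_all[k] * n
    postop = TriMesh(
        postop_vertices,
        case.mesh.faces.copy(),
        face_tags={k: v.copy() for k, v in case.mesh.face_tags.items()},
    )

    # --- ground-truth frame transforms -------------------------------------
    t_patient_image = _random_rigid(rng, 40.0, PATIENT_DRF, IMAGE)
    t_patient_tracker = _random_rigid(rng, 300.0, PATIENT_DRF, TRACKER)
    tip = TipCalibration(np.array([0.0, 0.0, 150.0]))
    drill_rot = Rotation.random(
        random_state=np.random.RandomState(rng.integers(2**31))
    ).as_matrix()

    times = np.linspace(0.0, duration_s, n_poses)
    tip_truth_image = _scripted_tip_path(plan, times)

    # tip_tracker = T_image->tracker(tip_image); drill translation places
    # R_drill @ offset at that point
    t_image_tracker = compose(invert(t_patient_image), t_patient_tracker)
    tip_tracker = t_image_tracker.apply(tip_truth_image)
    drill_transforms = [
        RigidTransform(drill_rot, p - drill_rot @ tip.offset, DRILL_DRF, TRACKER)
        for p in tip_tracker
    ]
    patient_track = PoseTrack(
        np.array([times[0], times[-1]]), [t_patient_tracker, t_patient_tracker]
    )
    stream = PoseStream(
        {
            DRILL_DRF: PoseTrack(times, drill_transforms),
            PATIENT_DRF: patient_track,
        }
    )

    noisy_stream = None
    if noise.pose_trans_sd_mm > 0 or noise.pose_rot_sd_deg > 0:
        noisy_stream = add_pose_noise(
            stream, noise.pose_trans_sd_mm, noise.pose_rot_sd_deg,
            seed=int(rng.integers(2**31)),
        )

    # --- fiducials in both spaces ------------------------------------------
    fid_image = np.array(list(case.fiducials.values()))
    t_image_patient = invert(t_patient_image)
    fid_patient = t_image_patient.apply(fid_image)
    fid_patient_noisy = fid_patient + rng.normal(0.0, noise.fiducial_sd_mm, fid_patient.shape) \
        if noise.fiducial_sd_mm > 0 else fid_patient.copy()

    return SimulatedProcedure(
        case=case,
        plan=plan,
        postop=postop,
        residual_values_mm=residuals,
        residual_mean_mm=residual_mean_mm,
        residual_sd_mm=residual_sd_mm,
        stream=stream,
        noisy_stream=noisy_stream,
        tip=tip,
        times_s=times,
        tip_truth_image=tip_truth_image,
        t_patient_image=t_patient_image,
        t_patient_tracker=t_patient_tracker,
        fiducials_image=fid_image,
        fiducials_patient=fid_patient,
        fiducials_patient_noisy=fid_patient_noisy,
        noise=noise,
        seed=seed,
    )


def add_pose_noise(
    stream: PoseStream, trans_sd_mm: float, rot_sd_deg: float, seed: int = 0
) -> PoseStream:
    """Perturb every pose with independent zero-mean noise; the input stream
    is left untouched.  Translation noise is isotropic Gaussian (mm);
    rotation noise is a random-axis rotation with Gaussian angle (deg)."""
    rng = np.random.default_rng(seed)
    new_tracks = {}
    for frame, track in stream.tracks.items():
        perturbed = []
        for tf in track.transforms:
            t = tf.translation + rng.normal(0.0, trans_sd_mm, 3) if trans_sd_mm > 0 \
                else tf.translation.copy()
            R = tf.rotation
            if rot_sd_deg > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = np.deg2rad(rng.normal(0.0, rot_sd_deg))
                R = Rotation.from_rotvec(angle * axis).as_matrix() @ R
            perturbed.append(RigidTransform(R, t, tf.source_frame, tf.target_frame))
        new_tracks[frame] = PoseTrack(track.times.copy(), perturbed)
    return PoseStream(new_tracks)
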