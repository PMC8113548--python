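"""Paired-point registration, ICP, and the tracked frame graph."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from recontour.geometry import RigidTransform, compose, invert
from recontour.registration import (
    DRILL_DRF,
    IMAGE,
    PATIENT_DRF,
    TRACKER,
    CorrespondenceSet,
    DegenerateConfigurationError,
    DisconnectedFramesError,
    FrameGraph,
    PoseStream,
    PoseTrack,
    TimestampRangeError,
    TipCalibration,
    drill_tip_in_image,
    icp_refine,
    paired_point_register,
)

from conftest import random_rigid


def rotation_angle_deg(R: np.ndarray) -> float:
    return float(np.degrees(np.abs(Rotation.from_matrix(R).magnitude())))


class TestPairedPointRegister:
    def test_identity_when_target_equals_source(self, rng):
        pts = rng.normal(0, 30, (10, 3))
        t, fre = paired_point_register(CorrespondenceSet(pts, pts))
        assert t.is_close(RigidTransform.identity(t.source_frame, t.target_frame), tol=1e-12)
        assert fre < 1e-12

    def test_exact_recovery_seeded(self, rng):
        """100 random rigid motions recovered to 1e-9 from exact pairs."""
        for _ in range(100):
            truth = random_rigid(rng)
            src = rng.normal(0, 40, (10, 3))
            est, fre = paired_point_register(CorrespondenceSet(src, truth.apply(src)))
            assert fre < 1e-9
            assert np.abs(est.rotation - truth.rotation).max() < 1e-9
            assert np.abs(est.translation - truth.translation).max() < 1e-9

    def test_noisy_recovery(self):
        """Isotropic 0.3 mm target noise, 8 pairs: FRE lands in [0.15, 0.6] mm
        and the rotation is recovered within 1 degree."""
        rng = np.random.default_rng(77)
        truth = random_rigid(rng)
        src = rng.normal(0, 50, (8, 3))
        tgt = truth.apply(src) + rng.normal(0, 0.3, (8, 3))
        est, fre = paired_point_register(CorrespondenceSet(src, tgt))
        assert 0.15 <= fre <= 0.6
        assert rotation_angle_deg(est.rotation.T @ truth.rotation) < 1.0

    def test_proper_rotation_even_for_reflected_targets(self, rng):
        """Near-planar points with a mirrored target: the solution must still
        be a proper rotation (det +1), by flipping the smallest singular
        direction."""
        src = rng.normal(0, 30, (6, 3))
        src[:, 2] *= 0.01  # nearly planar
        tgt = src.copy()
        tgt[:, 2] = -tgt[:, 2]  # reflection
        est, _ = paired_point_register(CorrespondenceSet(src, tgt))
        assert np.linalg.det(est.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "source",
        [
            np.zeros((2, 3)),  # too few
            np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]]),  # duplicate
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
        ],
        ids=["too-few", "duplicate", "collinear"],
    )
    def test_degenerate_configurations_rejected(self, source):
        with pytest.raises(DegenerateConfigurationError):
            paired_point_register(CorrespondenceSet(source, source + 1.0))

    def test_equivariance(self, rng):
        """Pre-rotating both point sets by Q conjugates the solution and
        leaves the FRE unchanged."""
        src = rng.normal(0, 30, (9, 3))
        tgt = random_rigid(rng).apply(src) + rng.normal(0, 0.2, (9, 3))
        base, fre0 = paired_point_register(CorrespondenceSet(src, tgt))
        q = random_rigid(rng, trans_scale=0.0)
        est, fre1 = paired_point_register(CorrespondenceSet(q.apply(src), q.apply(tgt)))
        assert fre1 == pytest.approx(fre0, abs=1e-9)
        conj = q.rotation @ base.rotation @ q.rotation.T
        assert np.abs(est.rotation - conj).max() < 1e-9

    def test_optimality_against_random_candidates(self, rng):
        """No random rigid candidate beats the closed-form FRE."""
        src = rng.normal(0, 30, (12, 3))
        tgt = random_rigid(rng).apply(src) + rng.normal(0, 0.5, (12, 3))
        corr = CorrespondenceSet(src, tgt)
        _, fre = paired_point_register(corr)
        for _ in range(50):
            cand = random_rigid(rng)
            rms = np.sqrt(np.mean(np.sum((cand.apply(src) - tgt) ** 2, axis=1)))
            assert fre <= rms + 1e-12

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent cross-check of the rotation against scipy's Kabsch."""
        src = rng.normal(0, 30, (15, 3))
        tgt = random_rigid(rng).apply(src) + rng.normal(0, 0.4, (15, 3))
        est, _ = paired_point_register(CorrespondenceSet(src, tgt))
        rot_scipy, _ = Rotation.align_vectors(
            tgt - tgt.mean(axis=0), src - src.mean(axis=0)
        )
        assert np.abs(est.rotation - rot_scipy.as_matrix()).max() < 1e-9


class TestICP:
    def test_source_on_surface_converges_immediately(self, rng, phantom_case):
        idx = rng.integers(0, len(phantom_case.mesh.vertices), 60)
        src = phantom_case.mesh.vertices[idx]
        t, rms, info = icp_refine(src, phantom_case.mesh, RigidTransform.identity("IMAGE"))
        assert rms < 1e-6
        assert info["converged"]

    def test_recovers_small_displacement(self, rng, phantom_case):
        """A 5 mm / 5 degree displacement is undone within 0.1 mm / 0.1 deg."""
        idx = rng.integers(0, len(phantom_case.mesh.vertices), 120)
        src_true = phantom_case.mesh.vertices[idx]
        axis = np.array([0.2, 1.0, 0.1])
        axis /= np.linalg.norm(axis)
        disp = RigidTransform(
            Rotation.from_rotvec(np.deg2rad(5.0) * axis).as_matrix(),
            np.array([3.0, 0.0, 4.0]),  # a 5 mm shift
            "IMAGE",
            "IMAGE",
        )
        src = invert(disp).apply(src_true)
        est, rms, info = icp_refine(src, phantom_case.mesh, RigidTransform.identity("IMAGE"))
        err = compose(est, invert(disp))
        assert np.linalg.norm(err.translation) < 0.1
        assert rotation_angle_deg(err.rotation) < 0.1

    def test_rms_monotone_nonincreasing(self, rng, phantom_case):
        idx = rng.integers(0, len(phantom_case.mesh.vertices), 80)
        src = phantom_case.mesh.vertices[idx] + rng.normal(0, 1.0, (80, 3))
        _, _, info = icp_refine(src, phantom_case.mesh, RigidTransform.identity("IMAGE"))
        hist = np.array(info["rms_history"])
        assert np.all(np.diff(hist) <= 1e-12)


class TestPoseTrack:
    @staticmethod
    def _line_track():
        tfs = [
            RigidTransform(np.eye(3), [0, 0, 0], DRILL_DRF, TRACKER),
            RigidTransform(np.eye(3), [0, 0, 10], DRILL_DRF, TRACKER),
        ]
        return PoseTrack(np.array([0.0, 1.0]), tfs)

    def test_linear_translation_midpoint(self):
        mid = self._line_track().sample(0.5)
        assert np.allclose(mid.translation, [0, 0, 5])

    def test_exact_timestamps_return_exact_pose(self):
        track = self._line_track()
        assert np.allclose(track.sample(1.0).translation, [0, 0, 10])

    def test_out_of_range_rejected(self):
        with pytest.raises(TimestampRangeError):
            self._line_track().sample(2.0)

    def test_slerp_halfway_rotation(self):
        r0 = np.eye(3)
        r1 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        track = PoseTrack(
            np.array([0.0, 1.0]),
            [RigidTransform(r0, np.zeros(3), "a", "b"), RigidTransform(r1, np.zeros(3), "a", "b")],
        )
        mid = track.sample(0.5)
        assert rotation_angle_deg(mid.rotation) == pytest.approx(45.0, abs=1e-9)


class TestFrameGraph:
    @staticmethod
    def _simple_graph(rng):
        g = FrameGraph()
        g.add_static_edge(random_rigid(rng, source=PATIENT_DRF, target=TRACKER))
        g.add_static_edge(random_rigid(rng, source=DRILL_DRF, target=TRACKER))
        g.add_static_edge(random_rigid(rng, source=PATIENT_DRF, target=IMAGE))
        return g

    def test_resolve_self_is_identity(self, rng):
        g = self._simple_graph(rng)
        assert g.resolve(TRACKER, TRACKER).is_close(RigidTransform.identity(TRACKER))

    def test_path_symmetry(self, rng):
        g = self._simple_graph(rng)
        for a in (TRACKER, PATIENT_DRF, DRILL_DRF, IMAGE):
            for b in (TRACKER, PATIENT_DRF, DRILL_DRF, IMAGE):
                fwd = g.resolve(a, b)
                back = g.resolve(b, a)
                assert invert(back).is_close(fwd, tol=1e-9)

    def test_disconnected_frames_rejected(self, rng):
        g = FrameGraph()
        g.add_static_edge(random_rigid(rng, source=PATIENT_DRF, target=TRACKER))
        g.add_static_edge(random_rigid(rng, source="OTHER", target=IMAGE))
        with pytest.raises(DisconnectedFramesError):
            g.resolve(PATIENT_DRF, IMAGE)

    def test_cycle_consistency(self, rng):
        g = self._simple_graph(rng)
        # add a consistent closing edge DRILL_DRF -> IMAGE and check cycles
        closing = g.resolve(DRILL_DRF, IMAGE)
        g.add_static_edge(closing)
        assert g.check_cycles(tol=1e-6)

    def test_inconsistent_cycle_detected(self, rng):
        g = self._simple_graph(rng)
        closing = g.resolve(DRILL_DRF, IMAGE)
        bad = RigidTransform(closing.rotation, closing.translation + 1.0, DRILL_DRF, IMAGE)
        g.add_static_edge(bad)
        assert not g.check_cycles(tol=1e-6)


class TestDrillTip:
    def test_identity_chain(self):
        g = FrameGraph()
        for s, t in [(PATIENT_DRF, TRACKER), (DRILL_DRF, TRACKER), (PATIENT_DRF, IMAGE)]:
            g.add_static_edge(RigidTransform.identity(s, t))
        tip = TipCalibration([0.0, 0.0, 100.0])
        assert np.allclose(drill_tip_in_image(g, tip, 0.0), [0, 0, 100])

    def test_simulator_ground_truth_noise_free(self, phantom_case, phantom_plan):
        """The full DRILL->TRACKER->PATIENT->IMAGE chain reproduces the
        scripted tip path exactly without noise."""
        from recontour.phantom import NoiseParams, simulate_procedure

        proc = simulate_procedure(
            phantom_case, phantom_plan, noise=NoiseParams(0, 0, 0), seed=11, n_poses=40
        )
        g = FrameGraph()
        g.add_static_edge(proc.t_patient_image)
        g.add_stream(proc.stream)
        tips = np.array([drill_tip_in_image(g, proc.tip, t) for t in proc.times_s])
        assert np.abs(tips - proc.tip_truth_image).max() < 1e-9

    def test_tip_error_under_pose_noise(self, phantom_case, phantom_plan):
        """0.2 mm / 0.1 deg pose noise on a 150 mm tool: tip RMS error in
        [0.1, 0.8] mm over 1,000 samples."""
        from recontour.phantom import NoiseParams, simulate_procedure

        proc = simulate_procedure(
            phantom_case,
            phantom_plan,
            noise=NoiseParams(pose_trans_sd_mm=0.2, pose_rot_sd_deg=0.1, fiducial_sd_mm=0.0),
            seed=21,
            n_poses=1000,
        )
        g = FrameGraph()
        g.add_static_edge(proc.t_patient_image)
        g.add_stream(proc.noisy_stream)
        tips = np.array([drill_tip_in_image(g, proc.tip, t) for t in proc.times_s])
        rms = np.sqrt(np.mean(np.sum((tips - proc.tip_truth_image) ** 2, axis=1)))
        assert 0.1 <= rms <= 0.8


class TestPoseStreamIO:
    def test_csv_roundtrip(self, rng, tmp_path):
        times = np.linspace(0, 2, 5)
        tracks = {
            DRILL_DRF: PoseTrack(
                times, [random_rigid(rng, source=DRILL_DRF, target=TRACKER) for _ in times]
            ),
            PATIENT_DRF: PoseTrack(
                times, [random_rigid(rng, source=PATIENT_DRF, target=TRACKER) for _ in times]
            ),
        }
        stream = PoseStream(tracks)
        stream.to_csv(tmp_path / "poses.csv")
        back = PoseStream.read_csv(tmp_path / "poses.csv")
        for frame in tracks:
            for a, b in zip(tracks[frame].transforms, back.tracks[frame].transforms):
                assert a.is_close(b, tol=1e-9)
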