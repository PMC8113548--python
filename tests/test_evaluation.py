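"""Post-op alignment, paired-point sampling, and deviation statistics."""

import numpy as np
import pytest

from recontour.evaluation import (
    aggregate_cases,
    align_postop,
    deviation_stats,
    sample_paired_points,
)
from recontour.geometry import RigidTransform, TriMesh, compose, invert
from recontour.registration import CorrespondenceSet

from conftest import make_planar_patch, random_rigid

# Printed per-case mean deviations of the five clinical cases (mm), used as
# inputs for the aggregation checks.
CASE_MEANS = [1.277, 1.218, 1.525, 1.861, 1.326]


class TestAlignPostop:
    def test_identity_when_same_space(self, rng, phantom_case):
        pts = phantom_case.mesh.vertices[rng.integers(0, 2000, 8)]
        t = align_postop(
            phantom_case.mesh, phantom_case.mesh, CorrespondenceSet(pts, pts)
        )
        assert t.is_close(RigidTransform.identity("plan", "postop"), tol=1e-9)

    def test_recovers_known_rigid_motion(self, rng, phantom_case):
        truth = random_rigid(rng, source="plan", target="postop")
        moved = phantom_case.mesh.transformed(truth)
        pts = phantom_case.mesh.vertices[rng.integers(0, 2000, 6)]
        t = align_postop(moved, phantom_case.mesh, CorrespondenceSet(pts, truth.apply(pts)))
        delta = compose(t, invert(truth))
        assert np.abs(delta.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(delta.translation).max() < 1e-6

    def test_surgical_region_change_does_not_corrupt_alignment(
        self, rng, phantom_case, phantom_plan
    ):
        """Alignment built on unchanged bone survives the surgical-region
        deformation: residual error on unchanged landmarks < 0.05 mm."""
        from recontour.phantom import NoiseParams, simulate_procedure

        proc = simulate_procedure(
            phantom_case, phantom_plan, noise=NoiseParams(0, 0, 0), seed=31, n_poses=20
        )
        truth = random_rigid(rng, source="plan", target="postop")
        postop_moved = proc.postop.transformed(truth)
        fid = proc.fiducials_image  # on the unchanged region by construction
        t = align_postop(
            postop_moved,
            phantom_plan.preop,
            CorrespondenceSet(fid, truth.apply(fid)),
            refine=True,
        )
        err = np.linalg.norm(t.apply(fid) - truth.apply(fid), axis=1)
        assert err.max() < 0.05

    def test_warns_when_correspondence_on_surgical_area(self, phantom_plan):
        surgical_face = phantom_plan.resection_faces[0]
        p = phantom_plan.preop.triangles[surgical_face].mean(axis=0)
        fid = phantom_plan.preop.vertices[[0, 50, 100]]
        corr = CorrespondenceSet(np.vstack([fid, p]), np.vstack([fid, p]))
        with pytest.warns(UserWarning, match="surgical area"):
            align_postop(phantom_plan.preop, phantom_plan.preop, corr)


class TestSamplePairedPoints:
    def test_identical_meshes_give_zero_distances(self, planar_patch):
        pairs = sample_paired_points(planar_patch, planar_patch, n=100, seed=3)
        assert pairs.distances.max() < 1e-12

    def test_parallel_planes_analytic_distance(self):
        """Planned z=0 vs post-op z=0.7: every pair separation is 0.7 mm."""
        planned = make_planar_patch(10.0, 11, z=0.0)
        postop = make_planar_patch(10.0, 11, z=0.7)
        pairs = sample_paired_points(planned, postop, n=200, seed=4)
        assert len(pairs) == 200
        assert np.abs(pairs.distances - 0.7).max() < 1e-9

    def test_misses_discarded_counted_and_warned(self):
        """A post-op patch covering half the planned patch: rays from the
        uncovered half miss within the cutoff and are discarded."""
        planned = make_planar_patch(20.0, 11, z=0.0)
        postop = make_planar_patch(9.0, 6, z=0.5)  # covers ~a quarter
        with pytest.warns(UserWarning, match="missed"):
            pairs = sample_paired_points(planned, postop, n=300, seed=5)
        assert pairs.n_discarded > 0
        assert len(pairs) + pairs.n_discarded == 300

    def test_empty_region_rejected(self, planar_patch):
        with pytest.raises(Exception):
            sample_paired_points(planar_patch, planar_patch, region=np.array([], dtype=int))

    def test_known_residual_field_recovered_pointwise(
        self, phantom_case, phantom_plan
    ):
        """Pair distances reproduce the simulator's imposed residual field:
        the sampled mean sits within 3 sigma/sqrt(n) of the injected mean."""
        from recontour.phantom import NoiseParams, simulate_procedure

        proc = simulate_procedure(
            phantom_case, phantom_plan, residual_mean_mm=1.4, residual_sd_mm=0.7,
            noise=NoiseParams(0, 0, 0), seed=41, n_poses=20,
        )
        pairs = sample_paired_points(
            phantom_plan.planned_surface, proc.postop, n=500, seed=42
        )
        rep = deviation_stats(pairs)
        assert rep.mean_mm == pytest.approx(1.4, abs=3 * 0.7 / np.sqrt(500))


class TestDeviationStats:
    def test_all_zero(self):
        rep = deviation_stats(CorrespondenceSet(np.zeros((5, 3)), np.zeros((5, 3))))
        assert rep.min_mm == rep.max_mm == rep.mean_mm == rep.sd_mm == 0.0

    def test_hand_computed_values(self):
        src = np.zeros((3, 3))
        tgt = np.array([[1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        rep = deviation_stats(CorrespondenceSet(src, tgt), "hand")
        assert rep.min_mm == 1.0
        assert rep.max_mm == 3.0
        assert rep.mean_mm == 2.0
        assert rep.sd_mm == pytest.approx(0.8165, abs=5e-5)  # population SD

    def test_order_invariance(self, rng):
        src = rng.normal(0, 10, (50, 3))
        tgt = src + rng.normal(0, 1, (50, 3))
        perm = rng.permutation(50)
        a = deviation_stats(CorrespondenceSet(src, tgt))
        b = deviation_stats(CorrespondenceSet(src[perm], tgt[perm]))
        for attr in ("min_mm", "max_mm", "mean_mm", "sd_mm"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)

    def test_internal_consistency(self, rng):
        src = rng.normal(0, 10, (30, 3))
        tgt = src + rng.normal(0, 1, (30, 3))
        rep = deviation_stats(CorrespondenceSet(src, tgt))
        assert rep.min_mm <= rep.mean_mm <= rep.max_mm
        assert rep.sd_mm >= 0
        assert rep.mean_mm == pytest.approx(float(np.mean(rep.distances_mm)))

    def test_serialisation(self, rng, tmp_path):
        src = rng.normal(0, 10, (10, 3))
        rep = deviation_stats(CorrespondenceSet(src, src + 1.0), "c1")
        rep.to_json(tmp_path / "r.json")
        rep.distances_to_csv(tmp_path / "d.csv")
        import json

        d = json.loads((tmp_path / "r.json").read_text())
        assert d["case_id"] == "c1" and d["n_points"] == 10


class TestAggregateCases:
    def test_clinical_case_means_aggregate(self):
        """The five per-case means aggregate to 1.442 ± 0.234 mm (the grand
        mean to within one ulp of the printed precision, since the inputs are
        themselves rounded; the SD exactly, under the population convention)."""
        rep = aggregate_cases(CASE_MEANS)
        assert abs(rep.grand_mean_mm - 1.442) <= 0.001
        assert round(rep.grand_sd_mm, 3) == 0.234

    def test_population_vs_sample_sd_discriminates(self):
        """Sample SD of the same means is 0.261 — the conventions are
        distinguishable at the printed precision."""
        assert round(float(np.std(CASE_MEANS, ddof=1)), 3) == 0.261
        assert round(float(np.std(CASE_MEANS)), 3) == 0.234

    def test_single_case(self):
        rep = aggregate_cases([1.5])
        assert rep.grand_mean_mm == 1.5 and rep.grand_sd_mm == 0.0

    def test_equal_cases_have_zero_sd(self):
        assert aggregate_cases([2.0, 2.0, 2.0]).grand_sd_mm == 0.0

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            aggregate_cases([])


class TestRigidInvariance:
    def test_report_invariant_under_common_rigid_motion(
        self, rng, phantom_case, phantom_plan
    ):
        """Moving plan and post-op together (and re-aligning) leaves the
        deviation statistics unchanged."""
        from recontour.phantom import NoiseParams, simulate_procedure

        proc = simulate_procedure(
            phantom_case, phantom_plan, noise=NoiseParams(0, 0, 0), seed=51, n_poses=20
        )
        base = deviation_stats(
            sample_paired_points(phantom_plan.planned_surface, proc.postop, n=300, seed=52)
        )
        t = random_rigid(rng, source="IMAGE", target="IMAGE")
        moved_plan = phantom_plan.planned_surface.transformed(t)
        moved_postop = proc.postop.transformed(t)
        moved = deviation_stats(sample_paired_points(moved_plan, moved_postop, n=300, seed=52))
        assert moved.mean_mm == pytest.approx(base.mean_mm, abs=1e-6)
        assert moved.max_mm == pytest.approx(base.max_mm, abs=1e-6)
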