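# recontour

An offline, hardware-free toolkit for the computational core of augmented-reality
navigation in **craniofacial recontouring surgery**. Unilateral fibrous dysplasia
replaces normal bone with expanding fibro-osseous tissue, deforming one side of
the face; treatment shaves the excess bone back to a planned contour. The plan
is built by mirroring the healthy side across the midsagittal plane, and a
navigation system tracks the drill so the surgeon knows — in millimetres, in
real time — how much bone remains above the planned surface.

`recontour` implements that whole computational pipeline for surgeons,
biomedical engineers and navigation researchers, with the optical hardware and
head-mounted display replaced by file-based pose streams and logged guidance
states, and with a synthetic skull phantom providing exact ground truth for
every stage:

1. **Virtual planning** — least-squares midsagittal plane from anatomical
   landmarks, Householder mirroring of the healthy hemiface, per-vertex excess
   thickness and resection-region delineation, lesion volume.
2. **Registration** — closed-form paired-point rigid registration (Kabsch SVD
   with det +1 enforced) reporting the fiducial registration error
   FRE = √(1/N Σᵢ ‖R pᵢ + t − qᵢ‖²), ICP surface refinement, and a tracked
   coordinate-frame graph (TRACKER, PATIENT_DRF, DRILL_DRF, IMAGE) with
   Slerp/linear pose interpolation and drill-tip localisation.
3. **Guidance** — signed drill-tip distance d to the planned surface per pose
   sample, with the two-state display logic: GREEN while d > 1 mm, RED once
   d ≤ 1 mm (boundary red), and a sample-rate-independent transition log.
4. **Evaluation** — post-op mesh aligned to the plan via unchanged-region
   paired points, hundreds of area-uniform paired points along planned-surface
   normals in the surgical area, and per-case min/max/mean ± SD deviation
   statistics with cross-case aggregation (population SD).
5. **Synthetic phantom** — bilaterally symmetric ellipsoid "skull" with a
   unilateral Gaussian lesion bump of known height, exact landmarks and
   fiducials, scripted drill passes, and simulated post-op surfaces carrying a
   residual error field of prescribed mean and spread.

## Worked example

```python
from recontour import *

case = make_phantom(PhantomSpec(seed=42))          # 6 mm lesion bump, right side
plane = fit_midsagittal_plane(case.landmarks)
plan = build_plan(case.mesh, plane, affected_side="right")
print(len(plan.resection_faces), plan.excess_map.max(), excess_volume(plan))

proc = simulate_procedure(case, plan, residual_mean_mm=1.4, residual_sd_mm=0.7,
                          noise=NoiseParams(0, 0, 0), seed=42)
frames = FrameGraph(); frames.add_static_edge(proc.t_patient_image)
log = process_pose_stream(proc.stream, plan, frames, proc.tip)

pairs = sample_paired_points(plan.planned_surface, proc.postop, n=500, seed=42)
report = deviation_stats(pairs, case_id="phantom-42")
```

which prints:

```
resection faces : 133
max excess      : 5.82 mm
excess volume   : 6094 mm^3
guidance        : 240 samples, 46 RED, 1 transition(s)
deviation       : min 0.1442  max 2.8041  mean 1.412 ± 0.642 mm  (n=500)
```

Reading the numbers: the planner recovers the 6 mm bump (5.82 mm at the mesh
resolution) and its 133-face footprint exactly; the scripted shaving pass
crosses the 1 mm guidance threshold once (GREEN→RED) and stays red while the
drill works at the planned surface; and the evaluation pipeline, given a
post-op surface fabricated with a 1.4 ± 0.7 mm residual error field, reports a
mean deviation of 1.412 mm — the injected error recovered to within sampling
noise. The same commands are available from the shell via
`recontour phantom | plan | register | guide | evaluate`.

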