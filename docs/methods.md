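# Methods

This note records the models, conventions and numerical choices behind
`recontour`, and what the synthetic phantom does and does not establish about
behaviour on real patient data.

## Geometry and conventions

All geometry is in millimetres; guidance thresholds and deviation statistics
are of order 1 mm, so double precision leaves ~12 digits of headroom. Rigid
transforms are stored as rotation matrix + translation, validated to
orthonormality and det +1 within 1e-9 (reflections are rejected: tracked
anatomy never mirrors), serialised as unit quaternion (w, x, y, z) +
translation. Composition re-orthonormalises through an SVD projection so long
frame chains cannot drift out of the rigidity tolerance.

**Closest point and signed distance.** The closest-point query prunes with a
KD-tree over face centroids: for query p, with d₀ the exact distance to the
nearest-centroid face and h the largest centroid-to-vertex span over all
faces, any face achieving the global minimum d* ≤ d₀ has centroid within
d* + h ≤ d₀ + h of p, so restricting the exact per-triangle test (Ericson's
region classification) to that ball discards no achiever. Accelerated and
brute-force answers are therefore *bit-identical*, which the tests assert
directly; ties between equidistant faces break to the lowest face index in
both paths. The signed distance takes its sign from the pseudonormal at the
closest feature — face normal in the interior, averaged normals on an edge,
angle-weighted normals at a vertex — the weighting that classifies
inside/outside correctly on closed meshes. Positive means outside the surface
(for guidance: material still to remove), negative past it.

Meshes are welded at 1e-6 mm and faces below 1e-12 mm² dropped at load,
because STL files duplicate vertices per facet and carry slivers.

## Midsagittal plane and mirroring

The symmetry plane is fitted jointly from midline landmarks and left/right
pairs by minimising nᵀ(C − D)n over unit normals n, where C is the scatter of
midline points and pair midpoints about their centroid (which fixes the plane
point) and D the outer-product sum of pair axes (right − left). The solution
is the smallest-eigenvalue eigenvector; pairs are implicitly weighted by
squared separation, appropriate since widely spaced pairs constrain the axis
direction better. A relative eigen-gap below 1e-9 flags a rank-deficient
configuration (e.g. collinear midline points). The normal is oriented
anatomical left → right; with midline-only input the orientation is fixed by
making the largest normal component positive. No landmark vocabulary is
imposed beyond the `_l`/`_r` pairing convention.

Mirroring is the Householder reflection p ↦ p − 2((p−q)·n)n with face winding
reversed, so the mirrored mesh keeps outward normals and signed volume.

## Plan construction

Per-vertex excess on the affected side is the signed distance from the pre-op
surface to the mirrored surface, clamped at zero (nearest-point
correspondence rather than ray casting — robust for non-star-shaped lesions).
A face joins the resection region when all three vertices exceed the
membership threshold, default **0.5 mm**: below typical mirroring and
segmentation noise, so smaller excess is not credibly lesion. The planned
surface is the mirrored mesh restricted to faces overlying the resection
region (nearest-face membership). Excess volume integrates the vertex excess
against barycentric-lumped vertex areas — a prism summation, exact for
uniform thickness over a flat patch and within discretisation error
elsewhere.

## Registration

Paired-point registration is the closed-form SVD solution; when the optimal
orthogonal matrix would be a reflection the smallest-singular-value direction
is flipped, yielding the best proper rotation. FRE is the RMS (not mean)
residual, the standard image-guidance convention. Degeneracy (under three
pairs, duplicate or collinear sources) raises rather than returning an
arbitrary fit.

ICP alternates exact closest-point correspondence with the closed-form fit,
rejecting pairs beyond 5× the median distance each iteration (robustness to
partial overlap). Point-to-point ICP corrects tangential misalignment slowly
on smooth low-curvature surfaces — correspondences slide along the surface —
so the default budget is generous (max_iter 2000, stop when RMS improves by
under 1e-12 mm); runs starting near the optimum stop within a few iterations.
Non-convergence at the iteration cap is flagged, not fatal.

The frame graph joins TRACKER, PATIENT_DRF, DRILL_DRF and IMAGE with static
or time-stamped edges; resolution composes the BFS path, interpolating
tracked edges (translation linearly, rotation by Slerp on unit quaternions).
Cycle consistency is checkable to 1e-6 by comparing each edge against the
path that remains without it. The patient-to-image registration uses the same
paired-point machinery on fiducial/anatomical landmarks; tip calibration is
an input (pivot acquisition is out of scope).

## Guidance

State is a pure function of the current signed distance: GREEN iff d > 1.0 mm,
RED otherwise — the boundary value itself is red, and overshoot (d < 0) stays
red. No hysteresis by default (the two-rule display logic is taken literally);
a configurable band exists for noisy streams but defaults off. Transition
times are linearly interpolated between bracketing samples so the log is
independent of the sampling rate. Unresolvable poses are skipped and counted,
never silently dropped. The displayed value is the signed distance rounded to
0.01 mm.

## Evaluation

Post-op alignment registers unchanged-region paired points (plan space →
post-op space), optionally ICP-refined on points sampled from the unchanged
region only; a correspondence lying on the surgical area triggers a warning,
since shaved bone cannot anchor a rigid alignment. "Uniform" point generation
is area-uniform: faces drawn with probability proportional to area, positions
by the square-root barycentric trick, seeded. Each source point on the
planned surface is paired with the nearest intersection of the post-op mesh
along the planned surface's normal (both directions; planned-surface normals,
not post-op normals, define the ray). Rays with no hit within **10 mm** are
discarded and counted — larger gaps indicate correspondence failure, not
surgical deviation — with a warning above 20 % misses.

Reported distances are unsigned (observed minima are near zero, not
negative). All SDs use the population convention (÷ n): applied to the five
published per-case means (1.277, 1.218, 1.525, 1.861, 1.326 mm) it reproduces
the published cross-case spread of 0.234 mm, whereas the sample convention
gives 0.261 mm; per-case SDs over points use the same convention for
consistency, though the published per-case convention is not determinable.
Note the arithmetic mean of those five printed values is 1.4414 mm, one unit
in the last printed digit below the published 1.442 mm grand mean — the
published figure was evidently averaged from unrounded per-case means, so
recomputation from printed inputs can only agree to ±0.001.

## Synthetic phantom

The phantom is a subdivided icosphere scaled to a skull-scale ellipsoid
(semi-axes 60 × 85 × 75 mm laterally/anteroposteriorly/vertically, 5120 faces
at the default resolution), exactly mirror-symmetric about x = 0, with a
unilateral Gaussian bump h·exp(−(d/w)²) displacing vertices along the exact
ellipsoid normal (defaults h = 6 mm, w = 18 mm — a palpable zygomatic lesion).
Landmarks and fiducials are exact points of the ideal symmetric ellipsoid
placed away from the lesion. An ellipsoid rather than an anatomical mesh
keeps the repository download-free and every oracle analytic (plane, bump
height, labels, volume).

Simulated procedures deform the resection region onto the planned surface
plus a smooth residual field — a low-frequency random Fourier sum
standardised over the region vertices to exactly the requested mean and SD
(defaults 1.4 ± 0.7 mm, the magnitude of reported recontouring errors).
A two-ring collar of surrounding vertices is deformed onto the mirrored
surface the same way; without it, boundary faces would interpolate between
shaved and untouched bone and bias paired-point distances sampled near the
rim low. Drill passes are scripted (descending sweep over the region);
noise-free replay reproduces the scripted tip path to machine precision, and
optional pose noise (default 0.2 mm / 0.1°) and fiducial noise (0.3 mm) model
tracking and localisation error. All randomness derives from a single seed.

**What the phantom does not show.** The ellipsoid is smooth, closed and
noiseless: it exercises none of the segmentation artefacts, holes, teeth and
thin bony structures of real CT surfaces, its smoothness makes ICP slower
(and real, feature-rich anatomy easier) to register than the tests might
suggest, and the residual field is smoother than real drill chatter. Passing
tests establish algorithmic correctness and statistical calibration of the
pipeline, not clinical accuracy on patient data.

## Problem sizes and tolerances

Default problem sizes — a 5120-face phantom, 500 paired points per case, ten
simulated cases for the parameter-recovery study, 1000 queries for the
brute-force distance comparison — were chosen so the entire suite and the
acceptance script each complete in well under a minute on one CPU while
keeping Monte-Carlo standard errors an order of magnitude below the effects
being checked. Exact-arithmetic claims (brute-force equality, replay
determinism) are asserted bitwise; ground-truth recovery claims use explicit
tolerances stated with each test.
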