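# Methods

This note records the models, conventions and design choices behind
`orthoplan`, and what the synthetic phantom does and does not demonstrate.

## Coordinate frame and Euler convention

All geometry is in millimetres in a right-handed frame: +x toward the
patient's left ("left–right"), +y anterior ("advance–setback"), +z superior
("impaction–elongation"). Angles are degrees at every interface, radians
internally.

Pitch, roll and yaw are rotations about the fixed x, y and z axes with
composition `R = Rz(yaw) · Ry(roll) · Rx(pitch)`. Clinical sources name the
axes but rarely the order; at the angle magnitudes typical of orthognathic
plans (< 13°) the orders agree to first order, so the choice is benign, but
it is fixed and used everywhere (composition, decomposition, displacement
summaries, angular discrepancies). Decomposition is closed-form
(`roll = asin(−R[2,0])`, `pitch = atan2(R[2,1], R[2,2])`,
`yaw = atan2(R[1,0], R[0,0])`); at gimbal lock (|roll| = 90°) only
pitch ∓ yaw is determined, so yaw is set to zero, the remaining angle folded
into pitch, and the result flagged `gimbal_lock`.

Rigid superposition of paired points uses the SVD closed form with the
determinant correction, so reflections are never returned; fewer than three
pairs or a (near-)collinear source raises a degenerate-geometry error
because the rotation is not unique.

## Registration

**Trimmed ICP.** "ICP" is point-to-point iterative closest point with two
optional modifications: correspondences farther than `max_distance` are
rejected, and the worst `trim_fraction` (default 0.1) of the survivors is
discarded before the least-squares fit. With `trim_fraction = 0` and
`max_distance = ∞` the solver reduces to classic ICP. Nearest neighbours are
exact, via a k-d tree. Correspondence is vertex-to-vertex, not
point-to-surface — simpler, and adequate at the phantom's vertex densities;
on sparse real meshes a point-to-plane metric would converge faster and is a
known limitation. Iteration stops when the kept-pair RMS changes by less
than `tolerance` (default 1e-6 mm) or at `max_iterations` (default 100);
the per-iteration RMS history is returned so monotonicity is testable.

**Rigid CPD.** The moving points are centroids of an isotropic Gaussian
mixture generating the fixed points, plus a uniform outlier component of
weight `w` (default 0.1) over the fixed cloud's bounding volume. EM
alternates soft correspondences with the closed-form weighted rigid
(optionally scaled) fit; the isotropic variance is re-estimated each
iteration from responsibility-weighted residuals, and the negative
log-likelihood is non-increasing. Scale estimation is off by default: scan
and CT are both metric. Variance collapse below 1e-12 (exact overlap) is
reported as converged with a warning rather than an error.

**Dentition fusion** runs trimmed ICP of the scan vertices onto the CT
model, then rigid CPD seeded with the ICP result. Two practical points:

- The CPD *target is cropped* to CT vertices within 10 mm of the
  ICP-aligned scan. A scan covers only the dentition; fitting the mixture
  against the entire skull lets the non-corresponding anatomy (the cranium
  is several times larger than the arch) pull the closed-form update away
  from the true pose. Cropping to the overlap neighbourhood makes the
  refinement local, which is exactly its role after coarse ICP.
- Point sets larger than 600 are subsampled (seeded) for the quadratic CPD
  stage.

**Cranial-base registration** runs trimmed ICP restricted to the cranial
mask vertices. Because the pose difference between a simulation model and a
postoperative scan is arbitrary, ICP is restarted from the identity and
from the four proper-rotation principal-axes alignments of the two cranial
clouds, keeping the restart with the lowest RMS. The fixed-side cranial
region defaults to the *same vertex indices* as the moving-side mask; that
holds whenever the two models share vertex ordering (same segmentation
pipeline, or a synthetic perturbation) and an explicit `fixed_mask` is
accepted otherwise. Principal axes of the full fixed mesh are not usable:
the dental arch skews the moments.

## Head-pose recovery (POSIT)

The camera is a pinhole with focal length in pixels (default 2000) and a
principal point, and the fixed `FRONTAL_VIEW` rotation maps the head frame
into the camera frame of a frontal facial photograph (the camera looks at
the face along the anterior axis). POSIT is the classic iteration: solve
the scaled-orthographic system through the model-point pseudo-inverse, form
two scaled rotation rows, orthonormalise to a proper rotation, update the
perspective corrections `ε_i = (M₀Mᵢ · r₃)/T_z`, and repeat until the
corrections change by less than 1e-8 (cap 50 iterations). Model landmark
sets whose centered matrix has condition number above 1e6
(coplanar/collinear faces) are rejected — POSIT's pseudo-inverse is
unreliable there. For NHP reproduction only the recovered rotation,
expressed in the head frame (`FRONTAL_VIEW.T @ R_camera`), is applied to
the model: the natural head position is an orientation, not a location.

**Accuracy under pixel noise is geometry-limited.** With the default
photograph geometry (2000 px focal length, 1.5 m distance, the seven facial
landmarks whose depth spread is ~25 mm), 1 px Gaussian landmark noise
produces a median head-rotation error near 2° — and a full least-squares
reprojection minimiser does no better than ~1.9°, so this is an information
limit of the viewing geometry, not of POSIT. Half-degree accuracy from a
single photograph requires a longer effective focal length (higher-
resolution imagery) or landmarks with more depth spread. The unit suite
therefore checks POSIT against the least-squares optimum (within a factor
of two); one acceptance check retains the stricter half-degree bound and
documents its failure under these conditions.

## Planning

A plan is an ordered list of steps; order matters (translate, then rotate,
matching clinical workflow). A rotation step is specified by a center, a
target point and a goal point, and realises the *minimal rotation aligning
direction (target − center) with direction (goal − center)*: axis = their
unit cross product, angle = the angle between them, fixed point = center.
The goal therefore sets a direction, not a radius — |target − center| is
preserved. Anti-parallel target/goal directions leave the axis ambiguous
and raise an error rather than guessing. The plan's six-component summary
is the net transform's translation plus the Euler decomposition of its net
rotation.

Osteotomy cuts split crossing triangles at the plane and leave the cut
boundaries open (uncapped): the two pieces' surface areas sum exactly to
the input area, and segments are used only for displacement and
visualisation. A plane missing the mesh produces one empty piece and a
warning, not an error.

The maxillary occlusal plane passes through the mesiobuccal cusps of the
right and left first molars and the central-incisor midpoint (an explicit
landmark of that name, or the midpoint of the two incisor landmarks). Its
frame: x from right to left molar cusp, z the plane normal flipped into the
+z hemisphere (tie-break: +y when horizontal), y completing the
right-handed triad. The hemisphere tie-break makes the frame equivariant
under rotations that keep the occlusal normal in the upper hemisphere —
always the case for anatomical poses.

## Evaluation and statistics

Discrepancies are signed `postoperative − simulation` per landmark, with
absolute values and the per-landmark `RMS = √(dx² + dy² + dz²)`; signed
values are retained for correlation analyses. Angular discrepancy is the
Euler decomposition of `F_post · F_simᵀ` between occlusal frames. Summary
tables give mean and sample SD (n−1 denominator) of the signed and of the
absolute values. The bundled 24-patient planning cohort reproduces its
published summary at 2-decimal precision, with two documented source
inconsistencies: the published absolute left–right mean (1.16) recomputes
to 1.15, and the published absolute-SD row matches a population (n)
denominator although the signed row uses n−1; the package uses n−1
consistently.

ANOVA is one-way fixed-effects across direction/orientation groups (a
repeated-measures design over the same patients would also be defensible;
not implemented). Post-hoc comparison is pairwise two-sample t-tests with
Bonferroni correction. Pearson's r carries the two-sided t-based p-value.
The normality screen is a one-sample Kolmogorov–Smirnov test against a
normal with the sample mean and SD — no Lilliefors correction, so its
p-value is anti-conservative; it is a screening device, not an inferential
endpoint.

## Synthetic phantom

The phantom is deliberately non-anatomical: an ellipsoidal "cranium" with
distinct semi-axes (52/66/58 mm) plus low-frequency radial bumps (4 %), and
a swept-rectangle dental arch (radius 28 mm, sinusoidal cusp bumps) hanging
below it, carrying all vocabulary landmarks at plausible mm positions. The
bumps matter: a plain ellipsoid is near-rotationally-symmetric and gives
surface registration nothing to lock onto. Default resolution is ~800
vertices (a few-second test budget); generators are bit-reproducible per
seed, and each generator draws from its own namespaced stream so adding one
never shifts another's output.

Scan emulation extracts the arch submesh, drops a seeded fraction of faces
(partial overlap), adds Gaussian vertex jitter, and applies the inverse of
the ground-truth transform, so fusion must recover the truth. Photo
emulation perspective-projects rotated facial landmarks through the frontal
camera. Postoperative emulation displaces the maxilla region and its tooth/
occlusal landmarks by a six-component displacement (rotation about the
occlusal-frame origin, then translation), optionally noises the cranial
surface, and re-poses everything by an arbitrary global transform.

What passing these tests shows: the solvers recover known rigid motion in
the presence of partial overlap, noise, outliers and arbitrary re-posing,
at clinical magnitudes. What they do not show: performance on real CT
segmentations (topological noise, metal artifacts, soft-tissue surfaces),
point-to-surface correspondence quality on sparse meshes, or clinical
accuracy values, which depend on patient data this package cannot ship.

## Problem sizes and tolerances

Default test problem sizes — ~800-vertex phantoms, 200–500-point
registration clouds, 27-pose POSIT grids, 60–200 noise trials — keep the
full suite under a minute while leaving every solver's convergence
behaviour visible. Key tolerances: rotation orthonormality 1e-7 on
construction; superposition/ICP convergence 1e-6 mm; CPD objective 1e-8
relative; POSIT corrections 1e-8; recovery assertions follow the per-module
bounds stated in the tests.
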