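# orthoplan

A desk-scale geometry toolkit for **digital orthognathic-surgery planning,
simulation and accuracy evaluation**. Bimaxillary surgery moves osteotomised
jaw segments to planned positions; verifying that the executed surgery
matches the virtual plan requires a chain of 3D geometry operations, each of
which this package implements as an importable library plus a thin CLI:

1. **Dentition fusion** — optical dentition scans are registered onto
   CT-derived skeletal models (CT dentitions suffer metal artifacts) with
   trimmed, k-d-tree-accelerated iterative closest point (ICP) followed by
   rigid coherent point drift (CPD), an EM fit of a Gaussian-mixture
   correspondence model with an explicit uniform outlier component.
2. **Natural head position (NHP)** — the upright reference orientation is
   recovered from a single frontal photograph with the POSIT algorithm
   ("pose from orthography and scaling with iterations") on ≥ 4
   non-coplanar facial landmarks (pronasale, bilateral exocanthion,
   endocanthion, cheilion); only the rotation is applied to the CT model.
3. **Planning and simulation** — plane-cut virtual osteotomy, then ordered
   plan steps: translations along the left–right (*x*), advance–setback
   (*y*) and impaction–elongation (*z*) axes in mm, and rotations about a
   clinical center aligning a *target* direction onto a *goal* direction.
   The net transform summarises as six components (three translations,
   pitch/roll/yaw of the net rotation, `R = Rz(yaw)·Ry(roll)·Rx(pitch)`).
4. **Evaluation** — the postoperative model is registered to the simulation
   model on the cranial base (non-surgically exposed region), then
   per-landmark linear discrepancies `d = postop − sim` with
   `RMS = √(dx² + dy² + dz²)` are computed at the eight maxillary tooth
   landmarks, and angular discrepancies as the pitch/roll/yaw between the
   maxillary occlusal-plane frames of the two models; cohort statistics
   (signed/absolute mean ± SD, one-way ANOVA, Pearson correlation,
   Kolmogorov–Smirnov normality) summarise a study.

Patient CT data of this kind cannot be shared, so `orthoplan.fixtures`
generates every input as a stylised skull phantom with known ground truth:
registration, pose and evaluation accuracy are demonstrated by *parameter
recovery* rather than by clinical data.

## Worked example

Summarise the bundled 24-patient planning cohort (translations in mm,
rotations in degrees):

```python
>>> import orthoplan as op
>>> print(op.summarize_displacements(op.example_cohort()).round(2).to_string())
          left_right  advance_setback  impaction_elongation  pitch  roll   yaw
mean            0.11             0.37                  0.88   5.48  0.70 -0.35
sd              1.40             1.40                  1.98   3.18  2.63  1.79
abs_mean        1.15             1.00                  1.67   5.48  2.14  1.41
abs_sd          0.76             1.03                  1.35   3.18  1.62  1.12
```

The mean planned pitch of 5.48° reflects the typical counter-clockwise
maxillary rotation of bimaxillary plans; the signed left–right mean near
zero with 1.40 mm SD reflects symmetric correction of asymmetries.

Evaluate a synthetic "postoperative" case in which the maxilla of a phantom
was displaced by (0.61, 0.86, 1.00) mm and (1.43, 0.50, 0.58)° and the whole
model arbitrarily re-posed (emulating a second CT scan):

```python
>>> from orthoplan import fixtures as fx
>>> phantom = fx.make_skull_phantom(fx.PhantomSpec(seed=11))
>>> applied = op.Displacement6(0.61, 0.86, 1.00, 1.43, 0.50, 0.58)
>>> pose = op.RigidTransform(op.euler_compose((6, -9, 12)), [15, -10, 8])
>>> case = fx.make_postop_case(phantom.mesh, phantom.landmarks,
...                            phantom.maxilla_indices, applied, global_pose=pose)
>>> report = op.evaluate_case(phantom.mesh, phantom.landmarks,
...                           case.mesh, case.landmarks, case.cranial_indices)
>>> report.angular
AngularDiscrepancy(pitch=1.4299999999999629, roll=0.4999999999999956, yaw=0.5800000000000002)
>>> print(report.linear.round(3).head(2).to_string())
                  dx     dy     dz  abs_dx  abs_dy  abs_dz    rms
right incisor  0.531  0.818  1.235   0.531   0.818   1.235  1.573
left incisor   0.530  0.897  1.167   0.530   0.897   1.167  1.564
```

The cranial-base registration has removed the arbitrary global pose; the
occlusal-plane angles reproduce the applied rotation exactly, and the
per-landmark linear discrepancies equal the true landmark motion (they
differ from the plain translation because the applied rotation moves each
tooth landmark by a lever arm about the occlusal-frame origin).

The same stages are scriptable from a shell:

```bash
orthoplan fixtures make-case --seed 7 --out case/
orthoplan fuse --scan case/scan.stl --model case/model.stl --out fuse.json
orthoplan nhp  --model case/model.stl --landmarks case/landmarks.json \
               --photo case/photo_landmarks.json --out nhp.stl
orthoplan plan-apply --model case/model.stl --landmarks case/landmarks.json \
                     --plan case/plan.json --out sim.stl
orthoplan evaluate --sim case/model.stl --sim-lm case/landmarks.json \
                   --post case/postop.stl --post-lm case/postop_landmarks.json \
                   --mask case/cranial_mask.json --out report.csv
orthoplan summarize --table cohort.csv
```

## Layout

- `orthoplan.geometry` — rigid transforms, SVD superposition, Euler angles, planes
- `orthoplan.io` — STL (binary/ASCII) meshes, landmark JSON, vocabulary
- `orthoplan.registration` — trimmed ICP, rigid CPD, fusion, cranial-base registration
- `orthoplan.posit` — camera model, POSIT, NHP reproduction
- `orthoplan.planning` — osteotomy plane cut, plan steps, occlusal plane
- `orthoplan.evaluation` — discrepancy tables, summary statistics, tests
- `orthoplan.fixtures` — seeded phantom generators with ground truth
- `orthoplan.cli` — `orthoplan` console entry point

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
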