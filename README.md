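# confkin

Confidence-based multibody kinematics optimization (MKO) for markerless
motion capture.

## The problem

Multi-camera markerless motion capture usually triangulates 3D keypoints
from the 2D detections of a human pose estimation network, then fits an
articulated rigid-body model to the 3D points. With sparse rigs — two
cameras is the minimum for triangulation — this pipeline is brittle: if a
keypoint is missed in even one view, its 3D position cannot be
reconstructed and the whole frame's kinematics may be lost. Yet the
network produces much more than an argmax pixel: a full 2D confidence
heatmap per keypoint per camera.

`confkin` implements an MKO that works directly in the camera planes.
Each heatmap is modeled as an isotropic 2D Gaussian
C(x) = A·exp(−‖x − x̃‖² / 2σ²) (center x̃ at the argmax pixel, amplitude A
its confidence, spread σ in pixels estimated from the confidence profile
through the center), and the body model is fitted by maximizing the
modeled confidence of every model point projected into every camera:

    min_Q  Σⱼ Σₖ [ C̃ⱼₖ( p(Xmod,ⱼ(Q), Tₖ) ) + ε ]⁻¹    s.t.  h(Q) = 0

where Q stacks the natural coordinates of all segments (two points and
two unit vectors per segment, 12 numbers each), Xmod,ⱼ(Q) = Nⱼ·Qᵢ is the
j-th model point via its constant interpolation matrix, p is the pinhole
projection with calibration Tₖ, and h(Q) collects the rigid-body and
joint constraints (spherical hips/shoulders/ankles, hinge elbows/knees,
free torso–pelvis). Terms for undetected keypoints are simply dropped —
one camera's view of a keypoint is enough to keep its frame solvable.
The classical distance-based MKO (squared distances to
confidence-weighted-DLT triangulated points, with OpenPose-style
thresholding and gap filling) is implemented alongside as the baseline,
and a synthetic scene generator (feasible ground-truth motion, Gaussian
blobs, pixel noise, distractors, per-camera dropouts) makes every stage
testable without any video data.

Who it is for: biomechanics and movement-science researchers working
with sparse camera setups (sports fields, workplaces) who need joint
kinematics that survive keypoint dropouts, and anyone studying the use
of full heatmap information in kinematic model fitting.

## Worked example

```python
import numpy as np
from confkin.synth import SceneConfig, generate_scene
from confkin.solver import solve_sequence
from confkin.evaluation import coverage

# two cameras, 120 frames at 60 Hz; 10% of frames lose one keypoint in
# exactly one camera (triangulation impossible there)
cfg = SceneConfig(duration=2.0, occlusion_fraction=0.1, seed=7)
scene = generate_scene(cfg)

conf = solve_sequence(scene.confidence_specs(), scene.model)
dist = solve_sequence(scene.distance_specs(), scene.model)

err = max(np.linalg.norm(scene.model.point_positions(s.Q)
                         - scene.truth_points[f], axis=1).max()
          for f, s in enumerate(conf) if s.converged)
print(f"confidence-based coverage: {coverage(conf):.1f}%")
print(f"distance-based coverage:   {coverage(dist):.1f}%")
print(f"confidence-based worst point error: {err*1000:.3f} mm")
```

Output:

```
confidence-based coverage: 100.0%
distance-based coverage:   91.7%
confidence-based worst point error: 0.001 mm
```

The 12 scheduled dropout frames form one 10-frame block — too long for
the 10-frame gap-fill rule, hence unrecoverable by triangulation and
skipped by the distance-based pipeline — plus a 2-frame remainder that
gap filling does recover (110 of 120 frames converged). The
confidence-based solver instead uses the remaining camera's Gaussian
term on every dropout frame and solves all 120, recovering the
ground-truth pose to about a micrometer on this noiseless scene.

A command-line interface wraps the same pipeline:

```bash
confkin synth --frames 120 --occlusion 0.1 --seed 7 --out scene/
confkin solve --mode confidence --calib scene/calibration.json \
    --model scene/model.json --gaussians scene/gaussians.csv --out conf/
confkin solve --mode distance --calib scene/calibration.json \
    --model scene/model.json --keypoints scene/keypoints --out dist/
confkin evaluate --ref dist/ --test conf/ --model scene/model.json --out report/
```

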