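# Methods

## Problem and model

`confkin` computes whole-body 3D kinematics from multi-camera 2D pose
observations by fitting an articulated rigid-body model per frame
(multibody kinematics optimization, MKO). The body is parameterized in
natural coordinates: each segment *i* carries twelve numbers
Qᵢ = (uᵢ, rPᵢ, rDᵢ, wᵢ) — two points (proximal, distal; meters) and two
unit vectors — and rigidity is expressed by six algebraic constraints
that pin ‖u‖², ‖w‖², ‖rP−rD‖² and the three mutual scalar products of
(u, rP−rD, w) to values calibrated once on a static pose. Squared-norm
forms are used so the residual is smooth at the constraint surface
(satisfied below 1e-8). Any point fixed in a segment is a constant linear
map of Qᵢ, X = N·Qᵢ, with N a 3×12 interpolation matrix built from the
point's coefficients (a, b, c) in the segment basis {u, rD−rP, w}
anchored at rP.

The default topology has 12 segments (pelvis, torso, upper arms,
forearms, thighs, shanks, three-point feet) and 19 driving points (neck,
shoulders, elbows, wrists, hips, knees, ankles, heels, big and small
toes). Hips, shoulders and ankles are spherical joints (3 coincidence
rows each); elbows and knees are hinges (3 coincidence rows plus 2 rows
holding the scalar products of the parent's hinge axis with the child's
longitudinal axis and with the child's w at their static values — the
hinge axis is the parent's medio-lateral w); torso–pelvis is a free
6-DOF joint contributing no rows. The ankle joint type is our choice
(spherical keeps the foot kinematically coupled when its keypoints drop
out); "arms" in the keypoint set end at the wrists, so no hands. Stacked,
h(Q) has 12·6 + 6·3 + 4·5 = 110 rows over 144 coordinates; the
constraint Jacobian is full-rank at feasible poses, leaving the expected
34 degrees of freedom (6 pelvis + 6 free torso + 2·(3+1+3) legs +
2·(3+1) arms).

A per-segment inequality keeps every frame direct:
det[u, (rP−rD)/‖rP−rD‖, w] ≥ bound. The middle column is normalized so a
direct orthonormal triad gives exactly +1 regardless of segment length.
Because the equalities already fix |det| at its calibrated value, a bound
at exactly that value would be degenerately active everywhere; the
default bound therefore sits a small margin (1e-6, configurable) below
the calibrated determinant, keeping the inequality inactive on the
feasible set while still excluding the mirrored (det = −1) branch.

## Objectives

*Distance-based MKO* (the classical baseline): min_Q Σⱼ ‖Xexp,ⱼ −
Xmod,ⱼ(Q)‖² subject to h(Q)=0, where Xexp,ⱼ are 3D points reconstructed
by confidence-weighted DLT (each camera's two homogeneous triangulation
rows scaled linearly by its detection confidence). Before triangulation,
2D trajectories are thresholded (confidence ≤ 0.05 invalid) and gaps
strictly shorter than 10 frames with valid neighbors on both sides are
filled by linear interpolation in pixel coordinates (interpolated
confidence = mean of the flanks); longer gaps and boundary gaps stay
invalid. A keypoint visible in fewer than two cameras cannot be
reconstructed, and a frame missing any required point is skipped — this
is the failure mode the confidence objective removes.

*Confidence-based MKO*: each keypoint's discrete confidence heatmap, per
camera, is modeled as an isotropic 2D Gaussian C(x) = A·exp(−‖x−x̃‖²/2σ²)
and the solver minimizes Σⱼ Σₖ (C̃ⱼₖ(p(Xmod,ⱼ(Q), Tₖ)) + ε)⁻¹ over the
*available* (keypoint, camera) terms, subject to the same constraints;
p is the pinhole projection with calibration Tₖ (no lens distortion
model). Undetected terms are simply omitted, so one camera's view of a
keypoint suffices — the robustness mechanism. The ε floor (default 1e-6,
configurable) bounds the reciprocal far from all Gaussians. The summed
reciprocal is the default reading; minimizing the negative summed
confidence (`objective_form="neg-sum"`) is an equivalent-intent variant
that weights lost terms linearly instead of hyperbolically.

## Gaussian heatmap fitting

The Gaussian center is the argmax pixel (ties broken toward the smallest
row, then column; no sub-pixel refinement), the amplitude is the maximum
value, and σ is the average of two line estimates within a 60×60-pixel
window clipped (never padded) at image borders: along the x and y lines
through the center, the confidence-weighted standard deviation of pixel
positions is computed; since truncation to the window biases that
statistic low once σ is no longer small against the half-window (about
−26% at σ = 20 px for a 60-px window), the estimator inverts the bias by
root-finding the σ whose model-implied windowed variance matches the
observed one. On noiseless rendered Gaussians this recovers σ exactly
(verified to <5% over σ ∈ [2, 20] px). Two alternative modes are kept
for comparison: the uncorrected weighted position std, and the standard
deviation of the confidence values themselves (a literal reading that
yields confidence units rather than pixels and is not used in the
objective). The window convention is exactly 60 px (±30 around the
center, right-exclusive). Model fidelity is quantified by absolute
differences between estimated and modeled maps within the same window
(pooled distribution and per-window maxima, with mean/std/quartiles/p99/
max summaries).

## Solver

Each frame is a smooth NLP in the 144 coordinates, solved with SLSQP
(SciPy) using analytic objective gradients and constraint Jacobians (all
constraints are at most quadratic in Q; the projection-Gaussian chain
rule is closed-form). Defaults: feasibility tolerance 1e-6 on ‖h‖∞,
SLSQP objective tolerance 1e-8, at most 1000 iterations. A frame counts
as converged only if the solver terminates cleanly *and* ‖h(Q*)‖∞ ≤ 1e-6
(the "positive directional derivative" line-search exit is accepted when
feasible — it indicates numerical stationarity). Inside the optimizer the
projection clamps depth at 1 mm so transient line-search probes behind a
camera stay finite; the public `project` raises instead.

Sequences are solved in order with warm starts: the first frame starts
from a data-driven guess (triangulated points in distance mode; DLT of
Gaussian centers where two cameras saw the keypoint in confidence mode;
static pose as last resort), later frames from the last converged
solution, so failed frames do not poison subsequent warm starts. Each
frame tries a short ladder — warm start, fresh data guess, static pose —
and keeps the first converged attempt. The initial guess sets rP/rD from
the experimental points and carries the calibrated static u, w over by
the minimal rotation aligning the static longitudinal axis to the
experimental one; completing u, w by Gram–Schmidt against a global axis
instead can land a basis 90° off its calibrated branch and traps the
optimizer in mirrored local minima (observed on cold starts), which is
why the rotation carry-over is used. Unresolvable segments inherit the
static coordinates rigidly attached to their parent's guess.

## Joint angles

Positions of shoulders, elbows, wrists, hips, knees, ankles and mid-toes
(midpoint of big and small toe) come from the interpolation matrices.
Segment frames are built per segment: Y along (rP−rD) normalized, X = u
orthogonalized against Y, Z completing the right-handed triad. Hip
angles use the mobile ZXY Euler sequence applied to the *change* of the
child-relative-to-parent rotation from the static pose — zero at the
static pose and, unlike the raw relative rotation between
differently-constructed frames, far from the ZXY gimbal singularity
through normal motion (the raw static offset sits at x ≈ −88°). Near
gimbal lock (|cos x| < 1e-8) the y = 0 branch is returned and flagged.
Knee and elbow flexion are signed rotations of the child longitudinal
axis about the calibrated hinge axis, zero at static; ankle FE is the
same construction about the shank's medio-lateral w (the ankle joint
itself is spherical). Shoulder orientation is azimuth/elevation of the
shoulder→elbow axis in the torso frame, both 0° with the arm extended
along the torso; elevation ∈ [0°, 180°]; azimuth is measured from the
torso's anterior axis in the transverse plane, reported as 0 exactly at
zero elevation and flagged below 5° elevation, where it is geometrically
meaningless. Angle trajectories are unwrapped with period 360°
(elevation excepted). All angles are zeroed by these conventions, not
offset-corrected to any marker-based convention.

## Synthetic scenes

The generator emulates a two-camera 60 Hz, 1920×1088 rig (cameras ~3.6 m
from the subject, between the frontal and sagittal planes). Ground-truth
motion is joint-space sinusoids propagated through the kinematic tree as
rigid transforms that pin every joint anchor and rotate hinges strictly
about their calibrated axes, so h(Q) = 0 holds to machine precision at
every frame (asserted) — closed-form, download-free references. The
default recipe keeps knees clearly flexed (28° ± 15°): at full knee
extension the thigh/shank axial spin is kinematically indeterminate (the
hinge dot rows are satisfied for any spin when the segments are
collinear), which would make ankle FE and hip internal rotation
ill-defined rather than merely inaccurate.

Per (frame, camera, keypoint) a Gaussian blob sits at the true
projection, with amplitude ~ U(0.7, 0.95) and σ ~ U(4, 10) px (the
well-detected regime of bottom-up pose estimators), optional center
jitter (pixel-noise std), optional value noise on rendered maps, and
optional weaker distractor blobs (second high-confidence areas). The
keypoint observation is the blob's argmax pixel with the blob amplitude
as confidence. The occlusion schedule drops exactly one keypoint in
exactly one camera for floor(fraction·n + 0.5) frames, grouped in
consecutive blocks of 10 frames (configurable) so the dropouts survive
gap filling and genuinely remove frames from the distance pipeline; a
shorter remainder block may be recovered by interpolation. One seed
fully determines a scene.

What the generator does not emulate: anisotropic or multi-modal heatmap
shapes beyond a single distractor blob, confidence degradation with
viewing angle, soft-tissue artifact, correlated detector failures, or
photorealistic appearance. Passing tests therefore demonstrate solver
and pipeline correctness under the stated noise and dropout models, not
pose-estimator accuracy on real video.

## Problem sizes and numerical defaults

Test suites use scenes of 6–200 frames; the headline robustness run uses
200 frames at 60 Hz with a 10% dropout fraction (two 10-frame blocks),
where the confidence-based pipeline converges on 100% of frames and the
triangulation pipeline on the remaining 90%. Noiseless recovery on these
scenes is ~0.03 mm in joint positions and well under 1° RMSE in joint
angles (pooled RMSE dominated by hip axial rotation, the least observable
DOF). Key defaults: confidence floor ε = 1e-6; feasibility 1e-6; SLSQP
ftol 1e-8 (1e-10 caused needless iteration-limit stalls); determinant
margin 1e-6; OpenPose-style validity threshold 0.05; gap-fill limit 10
frames; heatmap window 60 px.

## Known limitations

Local optimization only (no multi-frame coupling or global search);
isotropic single-Gaussian heatmap model; no lens distortion; linear wDLT
weighting (the confidence-squared variant is not implemented); axial
rotations of near-collinear chains are weakly observable by construction;
angle conventions are internally consistent but not offset-matched to
marker-based model conventions.
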