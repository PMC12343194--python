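"""Fully synthetic capture sessions for end-to-end testing without video.

A scene is a smooth, feasible whole-body motion (joint-space sinusoids
propagated through the kinematic tree, so every frame satisfies the
holonomic constraints to machine precision), viewed by a calibrated
multi-camera rig emulating a two-camera 60 Hz / 1920x1088 setup.  Each
(frame, camera, keypoint) gets a Gaussian confidence blob centered at the
true projection (optionally jittered), from which both pipelines consume
the same data: the distance pipeline reads argmax keypoint triplets in the
OpenPose JSON dialect, the confidence pipeline reads the Gaussian
parameters (or maps rendered from them).

Occlusions emulate the single-camera keypoint dropouts that break
triangulation: each scheduled frame loses exactly one keypoint in exactly
one camera, in consecutive blocks long enough to survive gap filling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraParams, look_at_camera, save_calibration
from .model import ModelDefinition, build_model_from_static, default_static_pose
from .natural_coords import transform_coordinates
from .solver import build_confidence_specs, build_distance_specs

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "default_cameras",
    "generate_motion",
    "occlusion_schedule",
    "render_scene",
    "generate_scene",
    "materialize_heatmap",
    "write_scene",
    "write_openpose_json",
    "read_openpose_json",
]


@dataclass
class SceneConfig:
    """Study conditions of one synthetic session.

    Defaults emulate the two-camera 60 Hz, 1920x1088 rig; amplitude and
    sigma ranges span the well-detected-keypoint regime of bottom-up pose
    estimators (high amplitude, blob spread of a few pixels).
    """

    frame_rate: float = 60.0
    duration: float = 5.0
    amplitude_range: tuple = (0.7, 0.95)
    sigma_range: tuple = (4.0, 10.0)
    pixel_noise_std: float = 0.0  # jitter of the blob center, pixels
    value_noise_std: float = 0.0  # additive noise on rendered map values
    occlusion_fraction: float = 0.0
    occlusion_block: int = 10  # consecutive frames per scheduled dropout
    distractor_rate: float = 0.0
    motion_amplitude: float = 1.0  # global scale on the joint-space sinusoids
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1]")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be > 0")
        if self.pixel_noise_std < 0 or self.value_noise_std < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


def default_cameras():
    """Two cameras between the frontal and sagittal planes of the subject."""
    return [
        look_at_camera("cam0", (3.2, -1.6, 1.4), (0.0, 0.0, 1.0)),
        look_at_camera("cam1", (3.2, 1.6, 1.4), (0.0, 0.0, 1.0)),
    ]


def _axis_angle(axis, theta: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def _rot_about_point(point, axis, theta):
    R = _axis_angle(axis, theta)
    return R, np.asarray(point, dtype=float) - R @ np.asarray(point, dtype=float)


def _compose(Ra, ta, Rb, tb):
    """(Ra, ta) o (Rb, tb): apply b first."""
    return Ra @ Rb, Ra @ tb + ta


# joint-space motion recipe: per joint, list of (world axis at static pose,
# mean deg, amplitude deg, frequency Hz, phase rad).  Axes for hinges MUST be
# the calibrated hinge axis; spherical joints may combine several axes.
_Y = (0.0, 1.0, 0.0)
_X = (1.0, 0.0, 0.0)
_Z = (0.0, 0.0, 1.0)

_MOTION_RECIPE = {
    "torso_pelvis": [(_Y, 0.0, 8.0, 0.35, 0.0)],
    "shoulder_r": [(_Y, 10.0, 22.0, 0.45, 0.0), (_X, 0.0, 8.0, 0.30, 1.0)],
    "shoulder_l": [(_Y, 10.0, 22.0, 0.45, np.pi), (_X, 0.0, 8.0, 0.30, 2.2)],
    "elbow_r": [("hinge", 25.0, 18.0, 0.45, 0.7)],
    "elbow_l": [("hinge", 25.0, 18.0, 0.45, 0.7 + np.pi)],
    "hip_r": [(_Y, 0.0, 22.0, 0.40, 0.0), (_X, 0.0, 6.0, 0.30, 0.5)],
    "hip_l": [(_Y, 0.0, 22.0, 0.40, np.pi), (_X, 0.0, 6.0, 0.30, 0.5 + np.pi)],
    # knees stay clearly flexed: at full extension thigh/shank axial spin is
    # kinematically indeterminate (hinge-axis dot rows degenerate), as in
    # real legs at hyperextension
    "knee_r": [("hinge", 28.0, 15.0, 0.40, 1.2)],
    "knee_l": [("hinge", 28.0, 15.0, 0.40, 1.2 + np.pi)],
    "ankle_r": [(_Y, 0.0, 9.0, 0.40, 2.0)],
    "ankle_l": [(_Y, 0.0, 9.0, 0.40, 2.0 + np.pi)],
}

# root (pelvis) motion: (translation amplitudes m, frequencies Hz), yaw deg
_ROOT_TRANSLATION = ((0.10, 0.05, 0.03), (0.20, 0.25, 0.70))
_ROOT_YAW = (8.0, 0.30)


def generate_motion(model: ModelDefinition, config: SceneConfig) -> np.ndarray:
    """Ground-truth coordinate trajectory, (n_frames, 12*nseg).

    Sinusoidal joint-space motion is propagated through the tree as rigid
    transforms that pin every joint anchor and rotate hinges strictly about
    their calibrated axes, so h(Q) = 0 holds to machine precision at every
    frame (asserted) and all segment frames stay direct.
    """
    F = config.n_frames
    amp = config.motion_amplitude
    t = np.arange(F) / config.frame_rate

    topo = model.topology
    seg_index = {s.name: i for i, s in enumerate(topo.segments)}
    child_joint = {}  # segment name -> JointSpec driving it
    for js in topo.joints:
        child_joint[js.child] = js

    # static joint anchors and hinge axes in world coordinates
    anchors, axes = {}, {}
    for js in topo.joints:
        j = model.joint_by_name(js.name)
        qp = model.static_q[j.parent]
        if j.Np is not None:
            anchors[js.name] = j.Np @ qp
        else:  # free joint: pivot about the child's distal point (mid-hip)
            anchors[js.name] = model.static_q[j.child][6:9]
        axes[js.name] = j.Na @ qp if j.Na is not None else None

    Q = np.empty((F, model.nq))
    root_idx = seg_index[topo.root]
    root_static = model.static_q[root_idx]
    root_mid = 0.5 * (root_static[3:6] + root_static[6:9])

    for f in range(F):
        tf = t[f]
        transforms = {}
        # root: translation + yaw about the vertical through the pelvis center
        (ax_t, fr_t), (yaw_amp, yaw_fr) = _ROOT_TRANSLATION, _ROOT_YAW
        trans = amp * np.array(
            [ax_t[d] * np.sin(2 * np.pi * fr_t[d] * tf + 0.4 * d) for d in range(3)]
        )
        Ry, ty = _rot_about_point(root_mid, _Z, np.radians(amp * yaw_amp) * np.sin(2 * np.pi * yaw_fr * tf))
        transforms[topo.root] = (Ry, ty + trans)

        for s in topo.segments:
            if s.name == topo.root:
                continue
            Rp, tp = transforms[s.parent]
            js = child_joint[s.name]
            R_j, t_j = np.eye(3), np.zeros(3)
            for axis_spec, mean_deg, amp_deg, freq, phase in _MOTION_RECIPE.get(js.name, []):
                axis = axes[js.name] if axis_spec == "hinge" else np.asarray(axis_spec, float)
                theta = np.radians(amp * (mean_deg + amp_deg * np.sin(2 * np.pi * freq * tf + phase)))
                Rr, tr = _rot_about_point(anchors[js.name], axis, theta)
                R_j, t_j = _compose(R_j, t_j, Rr, tr)
            transforms[s.name] = _compose(Rp, tp, R_j, t_j)

        for s in topo.segments:
            i = seg_index[s.name]
            R, tt = transforms[s.name]
            Q[f, model.seg_slice(i)] = transform_coordinates(model.static_q[i], R, tt)

        viol = np.max(np.abs(model.assemble_constraints(Q[f])))
        if viol > 1e-10:
            raise AssertionError(
                f"infeasible motion configuration at frame {f}: |h| = {viol:.2e}"
            )
    return Q


def occlusion_schedule(n_frames, keypoints, cameras, fraction, seed, block: int = 10):
    """Deterministic dropout schedule: {(frame, camera index, keypoint)}.

    ``floor(fraction * n_frames + 0.5)`` frames are scheduled, grouped in
    runs of ``block`` consecutive frames (the last run may be shorter);
    each run drops exactly one keypoint in exactly one camera, so
    triangulation fails there while the other view still sees the point.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_sched = int(np.floor(fraction * n_frames + 0.5))
    if n_sched == 0:
        return set()
    rng = np.random.default_rng(seed)
    keypoints = list(keypoints)
    n_cams = len(list(cameras))
    n_blocks = int(np.ceil(n_sched / block))
    # non-overlapping block start slots
    slots = np.arange(0, max(n_frames - block + 1, 1), block)
    starts = rng.choice(slots, size=min(n_blocks, len(slots)), replace=False)
    out = set()
    remaining = n_sched
    for s in sorted(starts):
        length = min(block, remaining, n_frames - s)
        kp = keypoints[int(rng.integers(len(keypoints)))]
        cam = int(rng.integers(n_cams))
        for f in range(s, s + length):
            out.add((f, cam, kp))
        remaining -= length
        if remaining <= 0:
            break
    return out


@dataclass
class SyntheticScene:
    """One rendered session: ground truth plus everything a pipeline reads."""

    config: SceneConfig
    model: ModelDefinition
    cameras: list
    names: list
    Q: np.ndarray  # (F, nq) ground-truth coordinates
    truth_points: np.ndarray  # (F, m, 3)
    gaussians: np.ndarray  # (F, ncam, m, 4): cx, cy, amplitude, sigma
    valid: np.ndarray  # (F, ncam, m) bool
    keypoints: np.ndarray  # (F, ncam, m, 3): x, y, confidence triplets
    occlusions: set = field(default_factory=set)
    distractors: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.Q.shape[0]

    def distance_specs(self, **kw):
        return build_distance_specs(self.keypoints, self.cameras, self.model, names=self.names, **kw)

    def confidence_specs(self):
        return build_confidence_specs(self.gaussians, self.valid, self.cameras, self.model, names=self.names)


def render_scene(
    traj: np.ndarray,
    model: ModelDefinition,
    cameras,
    config: SceneConfig,
) -> SyntheticScene:
    """Project a trajectory into every camera and attach confidence blobs.

    Per (frame, camera, keypoint): a Gaussian blob sits at the true
    projection plus optional center jitter, with amplitude and sigma drawn
    from the configured ranges; the keypoint observation is the blob's
    argmax pixel (the rounded center) with the blob amplitude as its
    confidence.  Occluded entries get a zero heatmap and confidence 0.
    """
    rng = np.random.default_rng(config.seed)
    names = list(model.point_names)
    F = traj.shape[0]
    m = len(names)
    ncam = len(cameras)
    occl = occlusion_schedule(
        F, names, cameras, config.occlusion_fraction,
        seed=int(rng.integers(2**31 - 1)), block=config.occlusion_block,
    )

    truth = np.empty((F, m, 3))
    gauss = np.zeros((F, ncam, m, 4))
    valid = np.zeros((F, ncam, m), dtype=bool)
    kps = np.zeros((F, ncam, m, 3))
    distractors = {}
    out_of_view = 0

    from .camera import project_points

    for f in range(F):
        X = model.point_positions(traj[f])
        truth[f] = X
        for k, cam in enumerate(cameras):
            px, depth = project_points(X, cam)
            amps = rng.uniform(*config.amplitude_range, size=m)
            sigmas = rng.uniform(*config.sigma_range, size=m)
            jitter = rng.normal(0.0, config.pixel_noise_std, size=(m, 2)) if config.pixel_noise_std > 0 else np.zeros((m, 2))
            centers = px + jitter
            for j, name in enumerate(names):
                if (f, k, name) in occl:
                    continue
                if depth[j] <= 0:
                    continue
                if not (0 <= px[j, 0] < cam.width and 0 <= px[j, 1] < cam.height):
                    out_of_view += 1
                gauss[f, k, j] = [centers[j, 0], centers[j, 1], amps[j], sigmas[j]]
                valid[f, k, j] = True
                kps[f, k, j] = [round(centers[j, 0]), round(centers[j, 1]), amps[j]]
                if config.distractor_rate > 0 and rng.random() < config.distractor_rate:
                    ang = rng.uniform(0, 2 * np.pi)
                    dist = rng.uniform(60.0, 250.0)
                    distractors[(f, k, name)] = (
                        centers[j, 0] + dist * np.cos(ang),
                        centers[j, 1] + dist * np.sin(ang),
                        amps[j] * rng.uniform(0.3, 0.8),
                        sigmas[j] * rng.uniform(0.8, 1.5),
                    )
    if out_of_view:
        warnings.warn(f"{out_of_view} keypoint projections fell outside the image bounds")
    return SyntheticScene(
        config=config, model=model, cameras=list(cameras), names=names,
        Q=traj, truth_points=truth, gaussians=gauss, valid=valid,
        keypoints=kps, occlusions=occl, distractors=distractors,
    )


def generate_scene(config: SceneConfig, model: ModelDefinition | None = None, cameras=None) -> SyntheticScene:
    """Convenience wrapper: default model and rig, motion, then rendering."""
    if model is None:
        model = build_model_from_static(default_static_pose())
    if cameras is None:
        cameras = default_cameras()
    traj = generate_motion(model, config)
    return render_scene(traj, model, cameras, config)


def materialize_heatmap(scene: SyntheticScene, frame: int, cam: int, keypoint: str, shape=None) -> np.ndarray:
    """Render the discrete confidence map of one (frame, camera, keypoint).

    Main blob, optional distractor blob (combined by maximum) and optional
    clipped value noise; occluded entries give an all-zero map.
    """
    from .heatmap import GaussianModel, render_gaussian

    camp = scene.cameras[cam]
    if shape is None:
        shape = (camp.height, camp.width)
    j = scene.names.index(keypoint)
    if not scene.valid[frame, cam, j]:
        return np.zeros(shape)
    cx, cy, A, s = scene.gaussians[frame, cam, j]
    hm = render_gaussian(GaussianModel(np.array([cx, cy]), A, s), shape)
    if (frame, cam, keypoint) in scene.distractors:
        dx, dy, dA, ds = scene.distractors[(frame, cam, keypoint)]
        if 0 <= dx < shape[1] and 0 <= dy < shape[0]:
            hm = np.maximum(hm, render_gaussian(GaussianModel(np.array([dx, dy]), dA, ds), shape))
    if scene.config.value_noise_std > 0:
        rng = np.random.default_rng((scene.config.seed, frame, cam, j))
        hm = np.clip(hm + rng.normal(0.0, scene.config.value_noise_std, size=shape), 0.0, 1.0)
    return hm


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_openpose_json(scene: SyntheticScene, outdir) -> None:
    """One JSON per frame per camera: people[0].pose_keypoints_2d triplets.

    Keypoints are flattened (x, y, confidence) in ``scene.names`` order;
    a ``keypoint_order.json`` file documents that order.
    """
    outdir = Path(outdir)
    for k in range(len(scene.cameras)):
        d = outdir / f"cam{k:02d}"
        d.mkdir(parents=True, exist_ok=True)
        for f in range(scene.n_frames):
            doc = {
                "version": 1.3,
                "people": [{"pose_keypoints_2d": [round(float(v), 4) for v in scene.keypoints[f, k].ravel()]}],
            }
            (d / f"{f:06d}_keypoints.json").write_text(json.dumps(doc))
    (outdir / "keypoint_order.json").write_text(json.dumps(scene.names))


def read_openpose_json(indir, names) -> np.ndarray:
    """Read per-frame per-camera keypoint files back to (F, ncam, m, 3)."""
    indir = Path(indir)
    cam_dirs = sorted(p for p in indir.iterdir() if p.is_dir() and p.name.startswith("cam"))
    per_cam = []
    for d in cam_dirs:
        frames = sorted(d.glob("*_keypoints.json"))
        arrs = []
        for fp in frames:
            doc = json.loads(fp.read_text())
            flat = doc["people"][0]["pose_keypoints_2d"] if doc["people"] else [0.0] * (3 * len(names))
            arrs.append(np.asarray(flat, dtype=float).reshape(len(names), 3))
        per_cam.append(np.stack(arrs))
    return np.stack(per_cam, axis=1)


def write_scene(scene: SyntheticScene, outdir) -> None:
    """Write calibration, model, keypoint JSONs, Gaussian table, ground truth."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_calibration(scene.cameras, outdir / "calibration.json")
    scene.model.to_json(outdir / "model.json")
    write_openpose_json(scene, outdir / "keypoints")

    rows = []
    for f in range(scene.n_frames):
        for k in range(len(scene.cameras)):
            for j, name in enumerate(scene.names):
                if scene.valid[f, k, j]:
                    cx, cy, A, s = scene.gaussians[f, k, j]
                    rows.append((f, k, name, cx, cy, A, s))
    pd.DataFrame(rows, columns=["frame", "cam", "keypoint", "cx", "cy", "amplitude", "sigma"]).to_csv(
        outdir / "gaussians.csv", index=False
    )

    rows = []
    for f in range(scene.n_frames):
        for j, name in enumerate(scene.names):
            x, y, z = scene.truth_points[f, j]
            rows.append((f, name, x, y, z))
    pd.DataFrame(rows, columns=["frame", "point", "x", "y", "z"]).to_csv(
        outdir / "ground_truth_points.csv", index=False
    )
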