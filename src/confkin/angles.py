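"""Joint positions and joint angles from optimized natural coordinates.

Conventions: hip (and generic ball-joint) angles use the mobile ZXY Euler
sequence of the change of the child-relative-to-parent orientation from the
static pose (so they read 0 at the static pose); elbow, knee and
ankle flexion/extension are signed hinge-style rotations about the parent's
medio-lateral axis, zero at the static pose; shoulder orientation is
reported as azimuth/elevation of the upper-arm longitudinal axis relative
to the torso, both zero with the arm fully extended along the torso.  The
azimuth is geometrically degenerate at zero elevation, so it is flagged
(and reported as 0 exactly at elevation 0) below a small elevation
threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ModelDefinition
from .natural_coords import segment_frame, vector_interpolation_matrix

__all__ = [
    "joint_positions",
    "euler_zxy",
    "shoulder_azimuth_elevation",
    "hinge_angle",
    "angle_frame",
    "angle_trajectories",
    "position_trajectories",
]

GIMBAL_COS_TOL = 1e-8
AZIMUTH_DEGENERACY_DEG = 5.0

#: joint-angle catalogue: name -> (kind, parent segment, child segment)
ANGLE_DEFS = {
    "hip_r": ("zxy", "pelvis", "thigh_r"),
    "hip_l": ("zxy", "pelvis", "thigh_l"),
    "knee_r": ("hinge", "thigh_r", "shank_r"),
    "knee_l": ("hinge", "thigh_l", "shank_l"),
    "ankle_r": ("hinge", "shank_r", "foot_r"),
    "ankle_l": ("hinge", "shank_l", "foot_l"),
    "shoulder_r": ("azel", "torso", "upper_arm_r"),
    "shoulder_l": ("azel", "torso", "upper_arm_l"),
    "elbow_r": ("hinge", "upper_arm_r", "forearm_r"),
    "elbow_l": ("hinge", "upper_arm_l", "forearm_l"),
}

_POSITION_POINTS = [
    "shoulder_r", "shoulder_l", "elbow_r", "elbow_l", "wrist_r", "wrist_l",
    "hip_r", "hip_l", "knee_r", "knee_l", "ankle_r", "ankle_l",
]


def joint_positions(Q, model: ModelDefinition) -> dict:
    """3D positions (meters) of the joints of interest, plus mid-toes.

    Mid-toe is the midpoint of the big-toe and small-toe model points.
    """
    out = {}
    for name in _POSITION_POINTS:
        if name in model.model_points:
            out[name] = model.point_position(Q, name)
    for side in ("r", "l"):
        big, small = f"big_toe_{side}", f"small_toe_{side}"
        if big in model.model_points and small in model.model_points:
            out[f"mid_toe_{side}"] = 0.5 * (
                model.point_position(Q, big) + model.point_position(Q, small)
            )
    return out


def euler_zxy(parent_R: np.ndarray, child_R: np.ndarray, return_flag: bool = False):
    """Mobile ZXY Euler angles (degrees) of Rrel = Rparent^T Rchild.

    Decomposes Rrel = Rz(z) Rx(x) Ry(y).  Near gimbal lock (|cos x| small)
    the y = 0 branch is returned and the flag (if requested) is set.
    """
    R = np.asarray(parent_R, dtype=float).T @ np.asarray(child_R, dtype=float)
    sx = np.clip(R[2, 1], -1.0, 1.0)
    x = np.arcsin(sx)
    gimbal = abs(np.cos(x)) < GIMBAL_COS_TOL
    if gimbal:
        y = 0.0
        z = np.arctan2(R[1, 0], R[0, 0])
    else:
        z = np.arctan2(-R[0, 1], R[1, 1])
        y = np.arctan2(-R[2, 0], R[2, 2])
    angles = np.degrees([z, x, y])
    return (angles, gimbal) if return_flag else angles


def shoulder_azimuth_elevation(torso_R: np.ndarray, humerus_axis, return_flag: bool = False):
    """Azimuth/elevation (degrees) of the upper-arm axis in the torso frame.

    ``humerus_axis`` points shoulder -> elbow.  Elevation is the angle from
    the torso's downward longitudinal axis, in [0, 180]; azimuth is the
    signed angle of the axis projected into the torso transverse plane,
    measured from the torso's anterior axis, positive toward the torso +Z
    (right).  Both are 0 with the arm hanging along the torso; the azimuth
    is reported as 0 exactly at zero elevation (degenerate projection) and
    flagged below a 5 degree elevation.
    """
    h = np.asarray(humerus_axis, dtype=float).reshape(3)
    nh = np.linalg.norm(h)
    if nh < 1e-12:
        raise ValueError("zero-length humerus axis")
    hl = np.asarray(torso_R, dtype=float).T @ (h / nh)  # torso-frame components
    elevation = float(np.degrees(np.arccos(np.clip(-hl[1], -1.0, 1.0))))
    if abs(hl[0]) < 1e-15 and abs(hl[2]) < 1e-15:
        azimuth = 0.0
    else:
        azimuth = float(np.degrees(np.arctan2(hl[2], hl[0])))
    flag = elevation < AZIMUTH_DEGENERACY_DEG
    return ((azimuth, elevation), flag) if return_flag else (azimuth, elevation)


def _hinge_axis_local(model: ModelDefinition, joint_name: str, parent_idx: int) -> np.ndarray:
    """Hinge (or pseudo-hinge) axis in the parent's orthonormal frame."""
    try:
        j = model.joint_by_name(joint_name)
        Na = j.Na
    except KeyError:
        Na = None
    if Na is None:
        # ankle-style pseudo-hinge: the parent's medio-lateral w axis
        Na = vector_interpolation_matrix((0.0, 0.0, 1.0))
    q_static = model.static_q[parent_idx]
    R0, _ = segment_frame(q_static)
    a = Na @ q_static
    return R0.T @ (a / np.linalg.norm(a))


def hinge_angle(q_parent, q_child, model: ModelDefinition, joint_name: str) -> float:
    """Signed rotation (degrees) of the child longitudinal axis about the
    hinge axis, measured relative to the static pose (0 there).

    Both axes are expressed in the parent frame, projected off the hinge
    axis, and compared against the static-pose reference projection.
    """
    _, pname, cname = _angle_def(model, joint_name)
    pi, ci = model.segment_index(pname), model.segment_index(cname)
    axis = _hinge_axis_local(model, joint_name, pi)

    def child_long_in_parent(qp, qc):
        Rp, _ = segment_frame(qp)
        v = qc[3:6] - qc[6:9]
        return Rp.T @ (v / np.linalg.norm(v))

    l_now = child_long_in_parent(np.asarray(q_parent, float), np.asarray(q_child, float))
    l_ref = child_long_in_parent(model.static_q[pi], model.static_q[ci])
    p0 = l_ref - (l_ref @ axis) * axis
    p1 = l_now - (l_now @ axis) * axis
    return float(np.degrees(np.arctan2(axis @ np.cross(p0, p1), p0 @ p1)))


def _angle_def(model: ModelDefinition, joint_name: str):
    if joint_name not in ANGLE_DEFS:
        raise KeyError(f"no angle definition for joint {joint_name!r}")
    kind, pname, cname = ANGLE_DEFS[joint_name]
    return kind, pname, cname


def angle_frame(Q, model: ModelDefinition) -> dict:
    """All catalogued joint angles for one frame: {(joint, dof): degrees}."""
    out = {}
    for joint, (kind, pname, cname) in ANGLE_DEFS.items():
        if pname not in model._seg_index or cname not in model._seg_index:
            continue
        qp = model.segment_q(Q, pname)
        qc = model.segment_q(Q, cname)
        if kind == "zxy":
            Rp, _ = segment_frame(qp)
            Rc, _ = segment_frame(qc)
            # decompose the change of relative orientation from the static
            # pose: zero at static, and (unlike the raw relative rotation
            # between differently-built segment frames) far from the ZXY
            # gimbal singularity through normal motion
            pi_, ci_ = model.segment_index(pname), model.segment_index(cname)
            R0p, _ = segment_frame(model.static_q[pi_])
            R0c, _ = segment_frame(model.static_q[ci_])
            R_rel = Rp.T @ Rc
            R0 = R0p.T @ R0c
            z, x, y = euler_zxy(np.eye(3), R_rel @ R0.T)
            out[(joint, "z")] = z
            out[(joint, "x")] = x
            out[(joint, "y")] = y
        elif kind == "hinge":
            out[(joint, "fe")] = hinge_angle(qp, qc, model, joint)
        elif kind == "azel":
            Rt, _ = segment_frame(qp)
            az, el = shoulder_azimuth_elevation(Rt, qc[6:9] - qc[3:6])
            out[(joint, "azimuth")] = az
            out[(joint, "elevation")] = el
    return out


def angle_trajectories(solutions, model: ModelDefinition, unwrap: bool = True) -> pd.DataFrame:
    """Long-format angle table over converged frames.

    Columns: frame, joint, dof, angle_deg.  With ``unwrap`` the angle time
    series are unwrapped (period 360) so flexion traces stay continuous
    across the +/-180 boundary; elevation (range [0, 180]) is left as is.
    """
    rows = []
    for f, sol in enumerate(solutions):
        if sol.Q is None or not sol.converged:
            continue
        for (joint, dof), val in angle_frame(sol.Q, model).items():
            rows.append((f, joint, dof, val))
    df = pd.DataFrame(rows, columns=["frame", "joint", "dof", "angle_deg"])
    if unwrap and len(df):
        for (joint, dof), grp in df.groupby(["joint", "dof"]):
            if dof == "elevation":
                continue
            df.loc[grp.index, "angle_deg"] = np.unwrap(grp["angle_deg"].to_numpy(), period=360.0)
    return df


def position_trajectories(solutions, model: ModelDefinition) -> pd.DataFrame:
    """Long-format 3D joint positions over converged frames (meters)."""
    rows = []
    for f, sol in enumerate(solutions):
        if sol.Q is None or not sol.converged:
            continue
        for name, X in joint_positions(sol.Q, model).items():
            rows.append((f, name, X[0], X[1], X[2]))
    return pd.DataFrame(rows, columns=["frame", "point", "x", "y", "z"])
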