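"""Whole-body model assembly from a static pose.

The body is a tree of rigid segments, each carrying 12 natural coordinates,
articulated by joints:

* ``spherical`` — 3 constraint rows forcing a parent-side and a child-side
  attachment point to coincide (hips, shoulders, ankles);
* ``hinge`` — 5 rows: 3 coincidence rows plus 2 rows holding the scalar
  products of the parent's hinge axis with the child's longitudinal axis
  and with the child's ``w`` vector at their static-pose values (elbows,
  knees);
* ``free6dof`` — 0 rows; the segments are coupled only through the
  objective (torso-pelvis).

All segment lengths, calibration dots, interpolation coefficients and joint
attachments are fixed once, from a single static pose given as 3D keypoint
positions, so that evaluating the model at that pose reproduces every input
point exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .natural_coords import (
    SegmentNaturalCoordinates,
    SegmentTemplate,
    frame_determinant,
    frame_determinant_gradient,
    interpolation_matrix,
    orthonormal_uw,
    rigid_body_constraints,
    rigid_body_jacobian,
    segment_frame,
    transform_coordinates,
    vector_interpolation_matrix,
)

__all__ = [
    "KEYPOINT_NAMES",
    "SegmentSpec",
    "JointSpec",
    "Topology",
    "default_topology",
    "default_static_pose",
    "ModelDefinition",
    "build_model_from_static",
    "initial_guess",
]

#: canonical keypoint order used throughout the package (OpenPose-style subset)
KEYPOINT_NAMES = [
    "neck",
    "shoulder_r",
    "shoulder_l",
    "elbow_r",
    "elbow_l",
    "wrist_r",
    "wrist_l",
    "hip_r",
    "hip_l",
    "knee_r",
    "knee_l",
    "ankle_r",
    "ankle_l",
    "heel_r",
    "heel_l",
    "big_toe_r",
    "big_toe_l",
    "small_toe_r",
    "small_toe_l",
]


@dataclass
class SegmentSpec:
    """One segment of a topology: anchors are keypoint names or 'mid:a,b'."""

    name: str
    proximal: str
    distal: str
    points: tuple = ()
    parent: str | None = None


@dataclass
class JointSpec:
    name: str
    jtype: str  # spherical | hinge | free6dof
    parent: str
    child: str
    anchor: str = ""
    axis: str = "w"  # hinge axis on the parent: 'u' | 'w'

    def __post_init__(self) -> None:
        if self.jtype not in ("spherical", "hinge", "free6dof"):
            raise ValueError(f"unknown joint type {self.jtype!r}")


@dataclass
class Topology:
    segments: list
    joints: list
    root: str = "pelvis"


def default_topology() -> Topology:
    """The 12-segment full-body layout used throughout.

    Torso, pelvis, upper arms, forearms (the keypoint set ends at the
    wrists, so no hands), thighs, shanks and three-point feet.  Hips,
    shoulders and ankles are spherical; elbows and knees are hinges about
    the parent's medio-lateral ``w`` axis; torso-pelvis is a free 6-DOF
    joint.  The neck and shoulders are driving points on the torso, not
    joints.
    """
    segs = [
        SegmentSpec("pelvis", "hip_r", "hip_l", ("hip_r", "hip_l")),
        SegmentSpec("torso", "neck", "mid:hip_r,hip_l", ("neck", "shoulder_r", "shoulder_l"), parent="pelvis"),
        SegmentSpec("upper_arm_r", "shoulder_r", "elbow_r", ("elbow_r",), parent="torso"),
        SegmentSpec("upper_arm_l", "shoulder_l", "elbow_l", ("elbow_l",), parent="torso"),
        SegmentSpec("forearm_r", "elbow_r", "wrist_r", ("wrist_r",), parent="upper_arm_r"),
        SegmentSpec("forearm_l", "elbow_l", "wrist_l", ("wrist_l",), parent="upper_arm_l"),
        SegmentSpec("thigh_r", "hip_r", "knee_r", ("knee_r",), parent="pelvis"),
        SegmentSpec("thigh_l", "hip_l", "knee_l", ("knee_l",), parent="pelvis"),
        SegmentSpec("shank_r", "knee_r", "ankle_r", ("ankle_r",), parent="thigh_r"),
        SegmentSpec("shank_l", "knee_l", "ankle_l", ("ankle_l",), parent="thigh_l"),
        SegmentSpec("foot_r", "heel_r", "mid:big_toe_r,small_toe_r", ("heel_r", "big_toe_r", "small_toe_r"), parent="shank_r"),
        SegmentSpec("foot_l", "heel_l", "mid:big_toe_l,small_toe_l", ("heel_l", "big_toe_l", "small_toe_l"), parent="shank_l"),
    ]
    joints = [
        JointSpec("torso_pelvis", "free6dof", "pelvis", "torso"),
        JointSpec("shoulder_r", "spherical", "torso", "upper_arm_r", "shoulder_r"),
        JointSpec("shoulder_l", "spherical", "torso", "upper_arm_l", "shoulder_l"),
        JointSpec("elbow_r", "hinge", "upper_arm_r", "forearm_r", "elbow_r"),
        JointSpec("elbow_l", "hinge", "upper_arm_l", "forearm_l", "elbow_l"),
        JointSpec("hip_r", "spherical", "pelvis", "thigh_r", "hip_r"),
        JointSpec("hip_l", "spherical", "pelvis", "thigh_l", "hip_l"),
        JointSpec("knee_r", "hinge", "thigh_r", "shank_r", "knee_r"),
        JointSpec("knee_l", "hinge", "thigh_l", "shank_l", "knee_l"),
        JointSpec("ankle_r", "spherical", "shank_r", "foot_r", "ankle_r"),
        JointSpec("ankle_l", "spherical", "shank_l", "foot_l", "ankle_l"),
    ]
    return Topology(segs, joints, root="pelvis")


def default_static_pose() -> dict:
    """A neutral standing pose (~1.6 m subject), world frame X anterior,
    Y left, Z up, origin on the floor between the feet; meters."""
    pose = {
        "neck": (0.00, 0.00, 1.50),
        "shoulder_r": (0.00, -0.18, 1.45),
        "shoulder_l": (0.00, 0.18, 1.45),
        "elbow_r": (0.01, -0.21, 1.16),
        "elbow_l": (0.01, 0.21, 1.16),
        "wrist_r": (0.02, -0.22, 0.90),
        "wrist_l": (0.02, 0.22, 0.90),
        "hip_r": (0.00, -0.09, 0.95),
        "hip_l": (0.00, 0.09, 0.95),
        "knee_r": (0.01, -0.10, 0.50),
        "knee_l": (0.01, 0.10, 0.50),
        "ankle_r": (0.00, -0.10, 0.09),
        "ankle_l": (0.00, 0.10, 0.09),
        "heel_r": (-0.06, -0.10, 0.05),
        "heel_l": (-0.06, 0.10, 0.05),
        "big_toe_r": (0.13, -0.08, 0.02),
        "big_toe_l": (0.13, 0.08, 0.02),
        "small_toe_r": (0.12, -0.13, 0.03),
        "small_toe_l": (0.12, 0.13, 0.03),
    }
    return {k: np.asarray(v, dtype=float) for k, v in pose.items()}


def _resolve_anchor(expr: str, points: dict) -> np.ndarray:
    """Resolve a keypoint name or 'mid:a,b' midpoint expression."""
    if expr.startswith("mid:"):
        names = expr[4:].split(",")
        vals = []
        for n in names:
            if n not in points or points[n] is None:
                raise KeyError(n)
            vals.append(np.asarray(points[n], dtype=float))
        return np.mean(vals, axis=0)
    if expr not in points or points[expr] is None:
        raise KeyError(expr)
    return np.asarray(points[expr], dtype=float)


@dataclass
class _Joint:
    """Runtime joint: attachment matrices and calibrated hinge dots."""

    name: str
    jtype: str
    parent: int
    child: int
    Np: np.ndarray | None = None  # 3x12 attachment on parent
    Nc: np.ndarray | None = None  # 3x12 attachment on child
    Na: np.ndarray | None = None  # 3x12 hinge-axis vector matrix (parent)
    c_long: float = 0.0  # axis . (rP_c - rD_c) at static
    c_w: float = 0.0  # axis . w_c at static

    @property
    def n_rows(self) -> int:
        return {"spherical": 3, "hinge": 5, "free6dof": 0}[self.jtype]


class ModelDefinition:
    """Segments, joints and model points of one subject's body model.

    Holds everything needed to evaluate the stacked holonomic constraints
    h(Q), their Jacobian, the direct-frame determinants, and the positions
    of all registered model points as linear maps of Q.
    """

    SCHEMA_VERSION = 1

    def __init__(self, topology: Topology, templates, static_q, joints, point_registry):
        self.topology = topology
        self.segment_names = [s.name for s in topology.segments]
        self._seg_index = {n: i for i, n in enumerate(self.segment_names)}
        self.templates = templates
        self.static_q = np.asarray(static_q, dtype=float)  # (nseg, 12)
        self.joints = joints
        # point_registry: name -> (segment_index, 3x12 interpolation matrix)
        self.model_points = point_registry
        self.point_names = list(point_registry)
        # stacked (3m, nq) matrix for vectorized point evaluation
        self._P = np.zeros((3 * len(self.point_names), self.nq))
        for j, name in enumerate(self.point_names):
            si, N = point_registry[name]
            self._P[3 * j : 3 * j + 3, 12 * si : 12 * si + 12] = N

    # -- basic layout -------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segment_names)

    @property
    def nq(self) -> int:
        return 12 * self.n_segments

    @property
    def n_points(self) -> int:
        return len(self.point_names)

    def segment_index(self, name: str) -> int:
        return self._seg_index[name]

    def seg_slice(self, i: int) -> slice:
        return slice(12 * i, 12 * i + 12)

    def segment_q(self, Q: np.ndarray, name_or_index) -> np.ndarray:
        i = name_or_index if isinstance(name_or_index, int) else self._seg_index[name_or_index]
        return np.asarray(Q, dtype=float).reshape(self.nq)[self.seg_slice(i)]

    def static_whole_q(self) -> np.ndarray:
        return self.static_q.reshape(-1).copy()

    def joint_by_name(self, name: str) -> _Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    # -- points -------------------------------------------------------
    def point_matrix(self, name: str) -> np.ndarray:
        return self.model_points[name][1]

    def point_segment(self, name: str) -> int:
        return self.model_points[name][0]

    def point_positions(self, Q: np.ndarray) -> np.ndarray:
        """(m, 3) positions of all model points, in registry order."""
        Q = np.asarray(Q, dtype=float).reshape(self.nq)
        return (self._P @ Q).reshape(-1, 3)

    def point_position(self, Q: np.ndarray, name: str) -> np.ndarray:
        si, N = self.model_points[name]
        return N @ self.segment_q(Q, si)

    @property
    def point_stack(self) -> np.ndarray:
        """The (3m, nq) stacked interpolation matrix."""
        return self._P

    # -- constraints ---------------------------------------------------
    @property
    def n_constraints(self) -> int:
        return 6 * self.n_segments + sum(j.n_rows for j in self.joints)

    def assemble_constraints(self, Q: np.ndarray) -> np.ndarray:
        """Stacked holonomic residual h(Q): rigid blocks then joint rows."""
        Q = np.asarray(Q, dtype=float).reshape(self.nq)
        h = np.empty(self.n_constraints)
        for i, tpl in enumerate(self.templates):
            h[6 * i : 6 * i + 6] = rigid_body_constraints(Q[self.seg_slice(i)], tpl)
        r = 6 * self.n_segments
        for j in self.joints:
            if j.jtype == "free6dof":
                continue
            qp = Q[self.seg_slice(j.parent)]
            qc = Q[self.seg_slice(j.child)]
            h[r : r + 3] = j.Np @ qp - j.Nc @ qc
            r += 3
            if j.jtype == "hinge":
                a = j.Na @ qp
                vc = qc[3:6] - qc[6:9]
                h[r] = a @ vc - j.c_long
                h[r + 1] = a @ qc[9:12] - j.c_w
                r += 2
        return h

    def constraint_jacobian(self, Q: np.ndarray) -> np.ndarray:
        Q = np.asarray(Q, dtype=float).reshape(self.nq)
        J = np.zeros((self.n_constraints, self.nq))
        for i in range(self.n_segments):
            J[6 * i : 6 * i + 6, self.seg_slice(i)] = rigid_body_jacobian(Q[self.seg_slice(i)])
        r = 6 * self.n_segments
        for j in self.joints:
            if j.jtype == "free6dof":
                continue
            ps, cs = self.seg_slice(j.parent), self.seg_slice(j.child)
            J[r : r + 3, ps] = j.Np
            J[r : r + 3, cs] = -j.Nc
            r += 3
            if j.jtype == "hinge":
                qp, qc = Q[ps], Q[cs]
                a = j.Na @ qp
                vc = qc[3:6] - qc[6:9]
                J[r, ps] = j.Na.T @ vc
                J[r, cs.start + 3 : cs.start + 6] = a
                J[r, cs.start + 6 : cs.start + 9] = -a
                J[r + 1, ps] = j.Na.T @ qc[9:12]
                J[r + 1, cs.start + 9 : cs.start + 12] = a
                r += 2
        return J

    # -- direct-frame inequality --------------------------------------
    def frame_determinants(self, Q: np.ndarray) -> np.ndarray:
        Q = np.asarray(Q, dtype=float).reshape(self.nq)
        return np.array([frame_determinant(Q[self.seg_slice(i)]) for i in range(self.n_segments)])

    def determinant_jacobian(self, Q: np.ndarray) -> np.ndarray:
        Q = np.asarray(Q, dtype=float).reshape(self.nq)
        J = np.zeros((self.n_segments, self.nq))
        for i in range(self.n_segments):
            J[i, self.seg_slice(i)] = frame_determinant_gradient(Q[self.seg_slice(i)])
        return J

    def determinant_bounds(self, margin: float = 1e-6) -> np.ndarray:
        """Per-segment lower bounds for the direct-frame inequality.

        The equality constraints already fix |det| at its calibrated value;
        the inequality only selects the direct branch, so the bound sits a
        small margin below the calibrated determinant to stay inactive at
        feasible configurations.
        """
        return np.array([t.calibrated_determinant() - margin for t in self.templates])

    # -- serialization -------------------------------------------------
    def to_json(self, path=None):
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "topology": {
                "root": self.topology.root,
                "segments": [
                    {"name": s.name, "proximal": s.proximal, "distal": s.distal,
                     "points": list(s.points), "parent": s.parent}
                    for s in self.topology.segments
                ],
                "joints": [
                    {"name": j.name, "jtype": j.jtype, "parent": j.parent,
                     "child": j.child, "anchor": j.anchor, "axis": j.axis}
                    for j in self.topology.joints
                ],
            },
            "templates": [
                {"name": t.name, "length": t.length, "dot_uv": t.dot_uv,
                 "dot_uw": t.dot_uw, "dot_vw": t.dot_vw,
                 "point_locals": {k: list(v) for k, v in t.point_locals.items()}}
                for t in self.templates
            ],
            "static_q": self.static_q.tolist(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, source) -> "ModelDefinition":
        if isinstance(source, (str, Path)):
            doc = json.loads(Path(source).read_text())
        else:
            doc = source
        if doc.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {doc.get('schema_version')}")
        topo = Topology(
            segments=[SegmentSpec(**s) for s in (dict(s, points=tuple(s["points"])) for s in doc["topology"]["segments"])],
            joints=[JointSpec(**j) for j in doc["topology"]["joints"]],
            root=doc["topology"]["root"],
        )
        templates = [
            SegmentTemplate(
                name=t["name"], length=t["length"], dot_uv=t["dot_uv"],
                dot_uw=t["dot_uw"], dot_vw=t["dot_vw"],
                point_locals={k: tuple(v) for k, v in t["point_locals"].items()},
            )
            for t in doc["templates"]
        ]
        static_q = np.asarray(doc["static_q"], dtype=float)
        return _assemble(topo, templates, static_q)


def _local_coeffs(point, rP, u, dvec, w) -> tuple:
    """Coefficients (a, b, c) with point = rP + a*u + b*dvec + c*w."""
    B = np.column_stack([u, dvec, w])
    return tuple(np.linalg.solve(B, np.asarray(point, dtype=float) - rP))


def _assemble(topology: Topology, templates, static_q) -> ModelDefinition:
    """Build runtime joint matrices and the point registry from templates."""
    seg_index = {s.name: i for i, s in enumerate(topology.segments)}
    tpl_by_name = {t.name: t for t in templates}

    point_registry = {}
    for s in topology.segments:
        tpl = tpl_by_name[s.name]
        for pname in s.points:
            point_registry[pname] = (seg_index[s.name], interpolation_matrix(tpl.point_locals[pname]))

    joints = []
    for js in topology.joints:
        pi, ci = seg_index[js.parent], seg_index[js.child]
        j = _Joint(js.name, js.jtype, pi, ci)
        if js.jtype != "free6dof":
            ptpl, ctpl = tpl_by_name[js.parent], tpl_by_name[js.child]
            j.Np = interpolation_matrix(ptpl.point_locals["__joint_" + js.name])
            j.Nc = interpolation_matrix(ctpl.point_locals["__joint_" + js.name])
        if js.jtype == "hinge":
            axis_coeffs = {"u": (1.0, 0.0, 0.0), "w": (0.0, 0.0, 1.0)}[js.axis]
            j.Na = vector_interpolation_matrix(axis_coeffs)
            qp = static_q[pi]
            qc = static_q[ci]
            a = j.Na @ qp
            j.c_long = float(a @ (qc[3:6] - qc[6:9]))
            j.c_w = float(a @ qc[9:12])
        joints.append(j)
    return ModelDefinition(topology, templates, static_q, joints, point_registry)


def build_model_from_static(static_points: dict, topology: Topology | None = None) -> ModelDefinition:
    """Calibrate a full model from one static pose.

    ``static_points`` maps keypoint names to 3-vectors (meters).  Segment
    lengths, calibration dots, interpolation coefficients and joint
    attachments are fixed so that the model evaluated at the static pose
    reproduces every input point to numerical precision.  Joints are
    defined directly from the keypoints (anchor expressions in the
    topology).
    """
    if topology is None:
        topology = default_topology()
    static_points = {k: np.asarray(v, dtype=float) for k, v in static_points.items()}

    templates = []
    static_q = np.zeros((len(topology.segments), 12))
    seg_index = {s.name: i for i, s in enumerate(topology.segments)}

    for i, s in enumerate(topology.segments):
        try:
            P = _resolve_anchor(s.proximal, static_points)
            D = _resolve_anchor(s.distal, static_points)
        except KeyError as e:
            raise ValueError(f"segment {s.name!r}: missing static keypoint {e.args[0]!r}") from None
        L = float(np.linalg.norm(P - D))
        if L < 1e-6:
            raise ValueError(f"segment {s.name!r}: zero-length (proximal == distal)")
        u, w = orthonormal_uw(P, D)
        q = np.concatenate([u, P, D, w])
        static_q[i] = q
        v = P - D
        tpl = SegmentTemplate(
            name=s.name, length=L,
            dot_uv=float(u @ v), dot_uw=float(u @ w), dot_vw=float(w @ v),
        )
        for pname in s.points:
            if pname not in static_points:
                raise ValueError(f"segment {s.name!r}: missing static keypoint {pname!r}")
            tpl.point_locals[pname] = _local_coeffs(static_points[pname], P, u, D - P, w)
        templates.append(tpl)

    tpl_by_name = {t.name: t for t in templates}
    for js in topology.joints:
        if js.jtype == "free6dof":
            continue
        try:
            anchor = _resolve_anchor(js.anchor, static_points)
        except KeyError as e:
            raise ValueError(f"joint {js.name!r}: missing static keypoint {e.args[0]!r}") from None
        for seg_name in (js.parent, js.child):
            q = static_q[seg_index[seg_name]]
            tpl_by_name[seg_name].point_locals["__joint_" + js.name] = _local_coeffs(
                anchor, q[3:6], q[0:3], q[6:9] - q[3:6], q[9:12]
            )

    model = _assemble(topology, templates, static_q)

    # self-consistency: the model must reproduce the static pose exactly
    Q0 = model.static_whole_q()
    for name in model.point_names:
        err = np.linalg.norm(model.point_position(Q0, name) - static_points[name])
        if err > 1e-10:
            raise AssertionError(f"static reconstruction failed for {name!r}: {err:.2e} m")
    if np.max(np.abs(model.assemble_constraints(Q0))) > 1e-10:
        raise AssertionError("static pose violates assembled constraints")
    return model


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation mapping unit vector a onto unit vector b."""
    c = float(a @ b)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about any axis perpendicular to a
        p = np.eye(3)[int(np.argmin(np.abs(a)))]
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def initial_guess(exp_points: dict, model: ModelDefinition) -> np.ndarray:
    """Estimate whole-body coordinates from (possibly partial) 3D points.

    Segments whose proximal and distal anchors are both available get
    rP/rD from the experimental points; u and w are the calibrated static
    vectors carried over by the minimal rotation that aligns the static
    longitudinal axis with the experimental one, which keeps every
    segment basis on the same branch as its calibration (a Gram-Schmidt
    completion from a fixed global axis can land 90 degrees off and trap
    the optimizer in mirrored local minima).  The result need not satisfy
    h(Q) = 0.  Unresolved segments inherit the static-pose coordinates
    rigidly attached to their parent's guess.
    """
    exp_points = {k: (None if v is None else np.asarray(v, dtype=float)) for k, v in exp_points.items()}
    nseg = model.n_segments
    Q = np.zeros(model.nq)
    resolved = [False] * nseg
    seg_index = {s.name: i for i, s in enumerate(model.topology.segments)}

    for i, s in enumerate(model.topology.segments):
        try:
            P = _resolve_anchor(s.proximal, exp_points)
            D = _resolve_anchor(s.distal, exp_points)
        except KeyError:
            continue
        if np.linalg.norm(P - D) < 1e-9:
            continue
        q_sta = model.static_q[i]
        v_sta = q_sta[3:6] - q_sta[6:9]
        R = _minimal_rotation(v_sta / np.linalg.norm(v_sta), (P - D) / np.linalg.norm(P - D))
        Q[model.seg_slice(i)] = np.concatenate([R @ q_sta[0:3], P, D, R @ q_sta[9:12]])
        resolved[i] = True

    for i, s in enumerate(model.topology.segments):
        if resolved[i]:
            continue
        if s.parent is None or not resolved[seg_index[s.parent]]:
            raise ValueError(
                f"segment {s.name!r}: anchors missing and no resolved parent to attach to"
            )
        pi = seg_index[s.parent]
        # rigid transform mapping the parent's static coordinates to its guess
        R_cur, _ = segment_frame(Q[model.seg_slice(pi)])
        R_sta, _ = segment_frame(model.static_q[pi])
        R = R_cur @ R_sta.T
        t = Q[model.seg_slice(pi)][3:6] - R @ model.static_q[pi][3:6]
        Q[model.seg_slice(i)] = transform_coordinates(model.static_q[i], R, t)
        resolved[i] = True
    return Q
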