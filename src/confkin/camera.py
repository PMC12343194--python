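"""Pinhole cameras, projection and (weighted) DLT triangulation.

Conventions: pixel coordinates are 0-based, origin at the top-left corner,
x rightward, y downward; integer coordinates address pixel centers.  The
extrinsics map world to camera coordinates (Xc = R X + t) with the optical
axis along +Z.  No lens distortion model is applied; a calibration file may
carry an optional ``distortion`` block, which the loader ignores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BehindCameraError",
    "CameraParams",
    "project",
    "project_points",
    "projection_jacobian",
    "triangulate_dlt",
    "triangulate_wdlt",
    "look_at_camera",
    "save_calibration",
    "load_calibration",
]

_ORTHO_TOL = 1e-10


class BehindCameraError(ValueError):
    """Raised when asked to project a point at non-positive depth."""


@dataclass
class CameraParams:
    """Intrinsic and extrinsic parameters of one pinhole camera."""

    name: str
    fx: float
    fy: float
    cx: float
    cy: float
    R: np.ndarray  # 3x3 world -> camera rotation
    t: np.ndarray  # 3-vector, camera = R X + t
    width: int = 1920
    height: int = 1088

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"camera {self.name!r}: focal lengths must be > 0")
        if np.max(np.abs(self.R @ self.R.T - np.eye(3))) > _ORTHO_TOL:
            raise ValueError(f"camera {self.name!r}: rotation is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > _ORTHO_TOL:
            raise ValueError(f"camera {self.name!r}: rotation determinant is not +1")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]])

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        return self.K @ np.hstack([self.R, self.t[:, None]])


def project(X, cam: CameraParams) -> np.ndarray:
    """Project a 3D world point (meters) to pixel coordinates.

    Raises :class:`BehindCameraError` for non-positive depth.
    """
    Xc = cam.R @ np.asarray(X, dtype=float).reshape(3) + cam.t
    if Xc[2] <= 0:
        raise BehindCameraError(f"camera {cam.name!r}: point at depth {Xc[2]:.3g} <= 0")
    return np.array([cam.fx * Xc[0] / Xc[2] + cam.cx, cam.fy * Xc[1] / Xc[2] + cam.cy])


def project_points(X: np.ndarray, cam: CameraParams, min_depth: float = 1e-3):
    """Vectorized projection of an (m, 3) array; depths clipped to ``min_depth``.

    Returns (pixels (m, 2), depths (m,)).  Unlike :func:`project` this never
    raises: it is the smooth evaluation path used inside the optimizer, where
    a line search may transiently probe small depths.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Xc = X @ cam.R.T + cam.t
    z = np.maximum(Xc[:, 2], min_depth)
    px = np.empty((X.shape[0], 2))
    px[:, 0] = cam.fx * Xc[:, 0] / z + cam.cx
    px[:, 1] = cam.fy * Xc[:, 1] / z + cam.cy
    return px, Xc[:, 2]


def projection_jacobian(X: np.ndarray, cam: CameraParams, min_depth: float = 1e-3) -> np.ndarray:
    """d(pixel)/d(world) for an (m, 3) array: (m, 2, 3) array of Jacobians."""
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Xc = X @ cam.R.T + cam.t
    z = np.maximum(Xc[:, 2], min_depth)
    m = X.shape[0]
    Jc = np.zeros((m, 2, 3))
    Jc[:, 0, 0] = cam.fx / z
    Jc[:, 0, 2] = -cam.fx * Xc[:, 0] / z**2
    Jc[:, 1, 1] = cam.fy / z
    Jc[:, 1, 2] = -cam.fy * Xc[:, 1] / z**2
    return Jc @ cam.R


def _dlt_rows(obs, cams, weights):
    A = []
    for x, cam, w in zip(obs, cams, weights):
        P = cam.P
        x = np.asarray(x, dtype=float).reshape(2)
        A.append(w * (x[0] * P[2] - P[0]))
        A.append(w * (x[1] * P[2] - P[1]))
    return np.array(A)


def triangulate_dlt(obs, cams) -> np.ndarray:
    """Linear least-squares triangulation of one 3D point from >= 2 views.

    Stacks the two homogeneous DLT equations per camera and takes the
    smallest right singular vector.
    """
    if len(obs) < 2 or len(cams) < 2:
        raise ValueError("triangulation requires observations from at least 2 cameras")
    A = _dlt_rows(obs, cams, np.ones(len(obs)))
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-12:
        raise ValueError("triangulation degenerate (point at infinity)")
    return Xh[:3] / Xh[3]


def triangulate_wdlt(obs, confidences, cams, min_confidence: float = 0.0) -> np.ndarray:
    """Confidence-weighted DLT: each camera's two rows scaled by its confidence.

    Cameras at or below ``min_confidence`` are dropped; with equal weights
    the result coincides with :func:`triangulate_dlt`.
    """
    keep = [i for i, c in enumerate(confidences) if c > min_confidence]
    if len(keep) < 2:
        raise ValueError(
            f"weighted triangulation requires >= 2 valid cameras, got {len(keep)}"
        )
    A = _dlt_rows(
        [obs[i] for i in keep], [cams[i] for i in keep], [confidences[i] for i in keep]
    )
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-12:
        raise ValueError("triangulation degenerate (point at infinity)")
    return Xh[:3] / Xh[3]


def look_at_camera(
    name: str,
    position,
    target,
    fx: float = 1000.0,
    fy: float = 1000.0,
    cx: float = 960.0,
    cy: float = 544.0,
    width: int = 1920,
    height: int = 1088,
    up=(0.0, 0.0, 1.0),
) -> CameraParams:
    """Camera at ``position`` looking at ``target`` with world +Z as up."""
    position = np.asarray(position, dtype=float)
    forward = np.asarray(target, dtype=float) - position
    forward = forward / np.linalg.norm(forward)
    up = np.asarray(up, dtype=float)
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-9:
        raise ValueError("camera looking along the up axis")
    right = right / nr
    down = np.cross(forward, right)
    R = np.vstack([right, down, forward])  # rows: camera x (right), y (down), z (forward)
    t = -R @ position
    return CameraParams(name, fx, fy, cx, cy, R, t, width, height)


def save_calibration(cams, path) -> None:
    doc = {
        "schema_version": 1,
        "cameras": [
            {
                "name": c.name,
                "image_size": [c.width, c.height],
                "K": c.K.tolist(),
                "R": c.R.tolist(),
                "t": c.t.tolist(),
            }
            for c in cams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_calibration(path):
    """Load a camera set from JSON; validates rotations, ignores distortion."""
    doc = json.loads(Path(path).read_text())
    cams = []
    for entry in doc["cameras"]:
        K = np.asarray(entry["K"], dtype=float)
        w, h = entry["image_size"]
        cams.append(
            CameraParams(
                name=entry["name"],
                fx=K[0, 0],
                fy=K[1, 1],
                cx=K[0, 2],
                cy=K[1, 2],
                R=np.asarray(entry["R"], dtype=float),
                t=np.asarray(entry["t"], dtype=float),
                width=int(w),
                height=int(h),
            )
        )
    return cams
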