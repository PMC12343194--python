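"""Natural-coordinate parameterization of rigid body segments.

A segment is described by 12 numbers: two points (proximal ``rP``, distal
``rD``, meters) and two unit vectors (``u``, ``w``, dimensionless).  Rigidity
is not enforced through a rotation parameterization but algebraically,
through six scalar constraints that pin the norms and mutual scalar products
of ``u``, ``v = rP - rD`` and ``w`` to values calibrated once on a static
pose.  Every kinematic quantity (point positions, joint couplings) is then
polynomial — at most quadratic — in the coordinates, which keeps objective
and constraint derivatives cheap and exact.

The position of any point rigidly attached to a segment is a fixed linear
map of the 12 coordinates: ``X = N @ q`` with ``N`` a constant 3x12
interpolation matrix.  Points are expressed in the (possibly non-orthogonal)
segment basis ``{u, rD - rP, w}`` anchored at ``rP``:

    X = rP + a*u + b*(rD - rP) + c*w

so ``N = [a*I3, (1-b)*I3, b*I3, c*I3]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentNaturalCoordinates",
    "SegmentTemplate",
    "interpolation_matrix",
    "vector_interpolation_matrix",
    "point_position",
    "rigid_body_constraints",
    "rigid_body_jacobian",
    "frame_determinant",
    "frame_determinant_gradient",
    "segment_frame",
    "orthonormal_uw",
    "transform_coordinates",
]

#: residual magnitude below which a configuration counts as constraint-satisfying
CONSTRAINT_TOL = 1e-8


@dataclass
class SegmentNaturalCoordinates:
    """The 12 natural coordinates (u, rP, rD, w) of one segment."""

    u: np.ndarray
    rP: np.ndarray
    rD: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).reshape(3)
        self.rP = np.asarray(self.rP, dtype=float).reshape(3)
        self.rD = np.asarray(self.rD, dtype=float).reshape(3)
        self.w = np.asarray(self.w, dtype=float).reshape(3)

    @classmethod
    def from_array(cls, q: np.ndarray) -> "SegmentNaturalCoordinates":
        q = np.asarray(q, dtype=float).reshape(12)
        return cls(q[0:3], q[3:6], q[6:9], q[9:12])

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 12-vector (u, rP, rD, w)."""
        return np.concatenate([self.u, self.rP, self.rD, self.w])

    @property
    def v(self) -> np.ndarray:
        """Longitudinal vector rP - rD (points distal -> proximal)."""
        return self.rP - self.rD


@dataclass
class SegmentTemplate:
    """Calibration constants of one segment, fixed at model building.

    ``length`` is |rP - rD| at the static pose; ``dot_uv``, ``dot_uw`` and
    ``dot_vw`` are the calibrated scalar products (with v = rP - rD) that the
    rigid-body constraints hold fixed.  ``point_locals`` maps model-point
    names to their (a, b, c) interpolation coefficients.
    """

    name: str
    length: float
    dot_uv: float = 0.0
    dot_uw: float = 0.0
    dot_vw: float = 0.0
    point_locals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.length) or self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be > 0, got {self.length}")
        for d in (self.dot_uv, self.dot_uw, self.dot_vw):
            if not np.isfinite(d):
                raise ValueError(f"segment {self.name!r}: non-finite calibration dot")
        if self.gram_determinant() <= 0:
            raise ValueError(
                f"segment {self.name!r}: degenerate basis (Gram determinant <= 0)"
            )

    def gram_matrix(self) -> np.ndarray:
        """Gram matrix of (u, v, w) implied by the calibration constants."""
        L2 = self.length**2
        return np.array(
            [
                [1.0, self.dot_uv, self.dot_uw],
                [self.dot_uv, L2, self.dot_vw],
                [self.dot_uw, self.dot_vw, 1.0],
            ]
        )

    def gram_determinant(self) -> float:
        return float(np.linalg.det(self.gram_matrix()))

    def calibrated_determinant(self) -> float:
        """|det[u, v/|v|, w]| implied by the calibration (mixed product / L)."""
        return float(np.sqrt(self.gram_determinant()) / self.length)


def interpolation_matrix(coeffs) -> np.ndarray:
    """Constant 3x12 matrix mapping q = (u, rP, rD, w) to a segment-fixed point.

    ``coeffs = (a, b, c)`` places the point at rP + a*u + b*(rD - rP) + c*w.
    """
    a, b, c = (float(x) for x in coeffs)
    eye = np.eye(3)
    return np.hstack([a * eye, (1.0 - b) * eye, b * eye, c * eye])


def vector_interpolation_matrix(coeffs) -> np.ndarray:
    """3x12 matrix mapping q to a segment-fixed *vector* a*u + b*(rD - rP) + c*w.

    Unlike :func:`interpolation_matrix` there is no rP anchor, so the result
    is translation-invariant (used for hinge axes and other directions).
    """
    a, b, c = (float(x) for x in coeffs)
    eye = np.eye(3)
    return np.hstack([a * eye, -b * eye, b * eye, c * eye])


def point_position(q, N: np.ndarray) -> np.ndarray:
    """Position of a segment point: exact matrix-vector product N @ q."""
    if isinstance(q, SegmentNaturalCoordinates):
        q = q.to_array()
    return N @ np.asarray(q, dtype=float).reshape(12)


def rigid_body_constraints(q, tpl: SegmentTemplate) -> np.ndarray:
    """The six rigid-body residuals of one segment.

    Squared-norm forms keep the residual smooth at the constraint surface:

        [|u|^2 - 1, |w|^2 - 1, |v|^2 - L^2, u.v - duv, u.w - duw, w.v - dvw]

    with v = rP - rD.  Zero iff the segment is at a rigid configuration
    consistent with the template.
    """
    if not isinstance(q, SegmentNaturalCoordinates):
        q = SegmentNaturalCoordinates.from_array(q)
    u, w, v = q.u, q.w, q.v
    return np.array(
        [
            u @ u - 1.0,
            w @ w - 1.0,
            v @ v - tpl.length**2,
            u @ v - tpl.dot_uv,
            u @ w - tpl.dot_uw,
            w @ v - tpl.dot_vw,
        ]
    )


def rigid_body_jacobian(q) -> np.ndarray:
    """6x12 Jacobian of :func:`rigid_body_constraints` (template-independent)."""
    if not isinstance(q, SegmentNaturalCoordinates):
        q = SegmentNaturalCoordinates.from_array(q)
    u, w, v = q.u, q.w, q.v
    J = np.zeros((6, 12))
    J[0, 0:3] = 2.0 * u
    J[1, 9:12] = 2.0 * w
    J[2, 3:6] = 2.0 * v
    J[2, 6:9] = -2.0 * v
    J[3, 0:3] = v
    J[3, 3:6] = u
    J[3, 6:9] = -u
    J[4, 0:3] = w
    J[4, 9:12] = u
    J[5, 9:12] = v
    J[5, 3:6] = w
    J[5, 6:9] = -w
    return J


def frame_determinant(q) -> float:
    """det[u, v/|v|, w] with v = rP - rD: +1 for a direct orthonormal triad.

    The middle column is normalized so that the direct-frame bound (>= 1 for
    orthonormal calibrations) is independent of segment length.
    """
    if not isinstance(q, SegmentNaturalCoordinates):
        q = SegmentNaturalCoordinates.from_array(q)
    v = q.v
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("degenerate segment: rP == rD")
    return float(q.u @ np.cross(v / nv, q.w))


def frame_determinant_gradient(q) -> np.ndarray:
    """12-vector gradient of :func:`frame_determinant` w.r.t. (u, rP, rD, w)."""
    if not isinstance(q, SegmentNaturalCoordinates):
        q = SegmentNaturalCoordinates.from_array(q)
    u, w, v = q.u, q.w, q.v
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("degenerate segment: rP == rD")
    vh = v / nv
    g = np.zeros(12)
    g[0:3] = np.cross(vh, w)
    g[9:12] = np.cross(u, vh)
    dvh = (np.eye(3) - np.outer(vh, vh)) / nv  # d(vhat)/d(v)
    dv = dvh @ np.cross(w, u)
    g[3:6] = dv
    g[6:9] = -dv
    return g


def segment_frame(q):
    """Orthonormal segment frame (R, origin) built from the coordinates.

    Y is the normalized longitudinal direction (rP - rD), X is u
    orthogonalized against Y, Z completes the right-handed triad; origin is
    rP.  Requires a direct (positive-determinant) configuration.
    """
    if not isinstance(q, SegmentNaturalCoordinates):
        q = SegmentNaturalCoordinates.from_array(q)
    if frame_determinant(q) <= 0:
        raise ValueError("indirect or degenerate segment triad")
    y = q.v / np.linalg.norm(q.v)
    x = q.u - (q.u @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("degenerate triad: u parallel to rP - rD")
    x = x / nx
    z = np.cross(x, y)
    R = np.column_stack([x, y, z])
    return R, q.rP.copy()


def orthonormal_uw(proximal: np.ndarray, distal: np.ndarray):
    """Build unit vectors u, w completing (proximal, distal) to a direct triad.

    u is the global axis least aligned with the longitudinal direction,
    Gram-Schmidt-orthogonalized; w = u x vhat, giving det[u, vhat, w] = +1
    and an orthonormal calibration (all template dots zero).
    """
    v = np.asarray(proximal, float) - np.asarray(distal, float)
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("coincident proximal and distal points")
    vh = v / nv
    axes = np.eye(3)
    g = axes[int(np.argmin(np.abs(axes @ vh)))]
    u = g - (g @ vh) * vh
    u = u / np.linalg.norm(u)
    w = np.cross(u, vh)
    return u, w


def transform_coordinates(q, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply the rigid transform x -> R x + t to a segment's coordinates.

    Vectors u, w rotate; points rP, rD rotate and translate.  Rigid-body
    residuals and the frame determinant are invariant under this map.
    """
    if isinstance(q, SegmentNaturalCoordinates):
        q = q.to_array()
    q = np.asarray(q, dtype=float).reshape(12)
    t = np.asarray(t, dtype=float).reshape(3)
    out = np.empty(12)
    out[0:3] = R @ q[0:3]
    out[3:6] = R @ q[3:6] + t
    out[6:9] = R @ q[6:9] + t
    out[9:12] = R @ q[9:12]
    return out
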