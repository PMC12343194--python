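"""Per-frame constrained multibody kinematics optimization (MKO).

Two objectives over the whole-body natural coordinates Q, both subject to
the stacked holonomic constraints h(Q) = 0 and the per-segment direct-frame
determinant inequalities:

* distance-based — sum of squared Euclidean distances between experimental
  3D points (triangulated from >= 2 cameras) and the model-derived points;
* confidence-based — for every available (keypoint, camera) pair, the model
  point is projected into that camera's image plane and evaluated under the
  Gaussian confidence surrogate; the sum of reciprocal confidences is
  minimized (equivalently, confidence is maximized).  Terms for undetected
  keypoints are simply omitted, which is what makes the method run even
  when a keypoint is seen by a single camera.

Each frame is a smooth NLP solved with SLSQP using analytic objective
gradients and constraint Jacobians; frames are warm-started from the
previous converged solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .camera import project_points, projection_jacobian, triangulate_wdlt
from .model import ModelDefinition, initial_guess

__all__ = [
    "SolverOptions",
    "ObjectiveSpec",
    "FrameSolution",
    "distance_objective",
    "confidence_objective",
    "solve_frame",
    "solve_sequence",
    "preprocess_keypoints",
    "build_distance_specs",
    "build_confidence_specs",
]

CONVERGED = "converged"
FAILED = "failed"
SKIPPED = "skipped_missing_data"


@dataclass
class SolverOptions:
    """Tolerances and knobs of the per-frame NLP.

    ``feas_tol`` is the max allowed |h(Q)| at a converged solution;
    ``ftol`` is the SLSQP objective stopping tolerance; ``eps`` is the
    floor added to the Gaussian confidence before taking the reciprocal
    (prevents blow-up far from all Gaussians); ``det_margin`` places the
    direct-frame lower bound just below each segment's calibrated
    determinant so the inequality only excludes the mirrored branch.
    """

    feas_tol: float = 1e-6
    ftol: float = 1e-8
    max_iter: int = 1000
    eps: float = 1e-6
    det_margin: float = 1e-6
    min_depth: float = 1e-3
    objective_form: str = "reciprocal-sum"  # or "neg-sum"


@dataclass
class ObjectiveSpec:
    """Data driving one frame's optimization.

    ``mode='distance'``: ``points`` maps keypoint name -> experimental
    3-vector (meters) or None when the point could not be reconstructed.
    ``mode='confidence'``: ``gaussians`` maps (keypoint name, camera index)
    -> GaussianModel; ``cameras`` is the camera list.
    """

    mode: str
    points: dict = field(default_factory=dict)
    gaussians: dict = field(default_factory=dict)
    cameras: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("distance", "confidence"):
            raise ValueError(f"unknown objective mode {self.mode!r}")

    def missing_points(self, required) -> list:
        return [n for n in required if self.points.get(n) is None]

    def under_constrained(self, required) -> bool:
        return len(self.missing_points(required)) > 0


@dataclass
class FrameSolution:
    """Optimized whole-body coordinates with convergence diagnostics."""

    Q: np.ndarray | None
    status: str
    objective: float = np.nan
    max_violation: float = np.nan
    n_iter: int = 0
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _distance_terms(spec: ObjectiveSpec, model: ModelDefinition):
    names = [n for n, v in spec.points.items() if v is not None]
    idx = np.array([model.point_names.index(n) for n in names], dtype=int)
    Xexp = np.array([np.asarray(spec.points[n], dtype=float) for n in names])
    return idx, Xexp


def _distance_value_grad(Q, spec, model):
    idx, Xexp = _distance_terms(spec, model)
    X = model.point_positions(Q)
    diff = X[idx] - Xexp
    f = float(np.sum(diff * diff))
    dX = np.zeros_like(X)
    dX[idx] = 2.0 * diff
    g = model.point_stack.T @ dX.ravel()
    return f, g


def distance_objective(Q, spec: ObjectiveSpec, model: ModelDefinition) -> float:
    """Sum over available points of squared distances |Xexp - Xmod(Q)|^2."""
    if spec.mode != "distance":
        raise ValueError("spec is not in distance mode")
    return _distance_value_grad(Q, spec, model)[0]


def _confidence_terms(spec: ObjectiveSpec, model: ModelDefinition):
    """Group Gaussian terms per camera: (cam_idx, point indices, centers, A, sigma)."""
    per_cam = {}
    for (kp, k), g in spec.gaussians.items():
        per_cam.setdefault(k, []).append((model.point_names.index(kp), g))
    out = []
    for k, terms in sorted(per_cam.items()):
        idx = np.array([t[0] for t in terms], dtype=int)
        centers = np.array([t[1].center for t in terms])
        amps = np.array([t[1].amplitude for t in terms])
        sigmas = np.array([t[1].sigma for t in terms])
        out.append((k, idx, centers, amps, sigmas))
    return out


def _confidence_value_grad(Q, spec, model, opts: SolverOptions):
    terms = _confidence_terms(spec, model)
    if not terms:
        raise ValueError("confidence objective has no available Gaussian terms")
    X = model.point_positions(Q)
    f = 0.0
    dX = np.zeros_like(X)
    reciprocal = opts.objective_form == "reciprocal-sum"
    for k, idx, centers, amps, sigmas in terms:
        cam = spec.cameras[k]
        px, _ = project_points(X[idx], cam, opts.min_depth)
        d = px - centers
        C = amps * np.exp(-np.sum(d * d, axis=1) / (2.0 * sigmas**2))
        if reciprocal:
            f += float(np.sum(1.0 / (C + opts.eps)))
            dfdC = -1.0 / (C + opts.eps) ** 2
        else:
            f += float(-np.sum(C))
            dfdC = -np.ones_like(C)
        # dC/dpx = -C * (px - center) / sigma^2
        dfdx = dfdC[:, None] * (-C[:, None] * d / sigmas[:, None] ** 2)
        Jx = projection_jacobian(X[idx], cam, opts.min_depth)  # (mk, 2, 3)
        np.add.at(dX, idx, np.einsum("kj,kji->ki", dfdx, Jx))
    return f, model.point_stack.T @ dX.ravel()


def confidence_objective(
    Q, spec: ObjectiveSpec, model: ModelDefinition, opts: SolverOptions | None = None
) -> float:
    """Sum over available (keypoint, camera) terms of reciprocal confidence.

    With every model point projecting exactly onto a unit-amplitude Gaussian
    center the value is (number of terms) / (1 + eps).  The ``neg-sum``
    variant returns minus the summed confidence instead (the prose reading
    of maximizing total confidence).
    """
    if spec.mode != "confidence":
        raise ValueError("spec is not in confidence mode")
    return _confidence_value_grad(Q, spec, model, opts or SolverOptions())[0]


# ---------------------------------------------------------------------------
# per-frame solve
# ---------------------------------------------------------------------------

def solve_frame(
    spec: ObjectiveSpec,
    q_init: np.ndarray,
    model: ModelDefinition,
    opts: SolverOptions | None = None,
) -> FrameSolution:
    """Solve one frame's constrained NLP from the given initial guess.

    Never raises on solver trouble: a non-converged frame is reported with
    status ``failed`` and diagnostics so a sequence run can continue.
    """
    opts = opts or SolverOptions()
    q_init = np.asarray(q_init, dtype=float).reshape(model.nq)

    if spec.mode == "distance":
        fun = lambda Q: _distance_value_grad(Q, spec, model)  # noqa: E731
    else:
        fun = lambda Q: _confidence_value_grad(Q, spec, model, opts)  # noqa: E731

    bounds_vec = model.determinant_bounds(opts.det_margin)
    constraints = [
        {"type": "eq", "fun": model.assemble_constraints, "jac": model.constraint_jacobian},
        {
            "type": "ineq",
            "fun": lambda Q: model.frame_determinants(Q) - bounds_vec,
            "jac": model.determinant_jacobian,
        },
    ]
    try:
        res = minimize(
            fun,
            q_init,
            jac=True,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": opts.max_iter, "ftol": opts.ftol},
        )
    except (ValueError, FloatingPointError) as e:  # pragma: no cover - defensive
        return FrameSolution(None, FAILED, message=f"solver exception: {e}")

    viol = float(np.max(np.abs(model.assemble_constraints(res.x))))
    # status 8 = "positive directional derivative for linesearch": the line
    # search cannot improve further; with feasibility met this is a solution
    # at numerical precision.
    ok = (res.success or res.status == 8) and viol <= opts.feas_tol
    return FrameSolution(
        Q=res.x,
        status=CONVERGED if ok else FAILED,
        objective=float(res.fun),
        max_violation=viol,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def _first_guess(spec: ObjectiveSpec, model: ModelDefinition) -> np.ndarray:
    """Initial coordinates for the first solvable frame of a sequence."""
    if spec.mode == "distance":
        pts = {k: v for k, v in spec.points.items() if v is not None}
    else:
        # DLT of Gaussian centers wherever >= 2 cameras saw the keypoint
        by_kp = {}
        for (kp, k), g in spec.gaussians.items():
            by_kp.setdefault(kp, []).append((k, g))
        pts = {}
        for kp, entries in by_kp.items():
            if len(entries) >= 2:
                obs = [g.center for _, g in entries]
                confs = [g.amplitude for _, g in entries]
                cams = [spec.cameras[k] for k, _ in entries]
                try:
                    pts[kp] = triangulate_wdlt(obs, confs, cams)
                except ValueError:
                    pass
    try:
        return initial_guess(pts, model)
    except ValueError:
        return model.static_whole_q()


def solve_sequence(
    specs,
    model: ModelDefinition,
    opts: SolverOptions | None = None,
    required_points=None,
) -> list:
    """Solve an ordered sequence of frames with warm starts.

    The first frame starts from an experimental initial guess (triangulated
    points, or DLT of Gaussian centers, falling back to the static pose);
    each later frame starts from the last converged solution, so failed
    frames do not poison subsequent warm starts.  Distance-mode frames with
    any unreconstructable required point are skipped outright; confidence
    frames are always attempted as long as one Gaussian term exists.
    """
    opts = opts or SolverOptions()
    if required_points is None:
        required_points = list(model.point_names)
    solutions = []
    warm = None
    for spec in specs:
        if spec.mode == "distance" and spec.under_constrained(required_points):
            missing = spec.missing_points(required_points)
            solutions.append(
                FrameSolution(None, SKIPPED, message=f"missing 3D points: {missing}")
            )
            continue
        if spec.mode == "confidence" and not spec.gaussians:
            solutions.append(FrameSolution(None, SKIPPED, message="no Gaussian terms"))
            continue
        # attempt ladder: warm start, then a fresh data-driven guess, then
        # the static pose; stop at the first converged attempt
        attempts = []
        if warm is not None:
            attempts.append(warm)
        attempts.append(_first_guess(spec, model))
        attempts.append(model.static_whole_q())
        sol = None
        for q0 in attempts:
            trial = solve_frame(spec, q0, model, opts)
            if sol is None or trial.converged:
                sol = trial
            if trial.converged:
                break
        if sol.converged:
            warm = sol.Q
        solutions.append(sol)
    return solutions


# ---------------------------------------------------------------------------
# distance-pipeline preprocessing
# ---------------------------------------------------------------------------

def preprocess_keypoints(series: np.ndarray, conf_threshold: float = 0.05, max_gap: int = 10):
    """Threshold and gap-fill 2D keypoint trajectories of one camera.

    ``series`` is (n_frames, n_keypoints, 3) with (x, y, confidence)
    triplets.  Observations with confidence <= ``conf_threshold`` are
    invalid; invalid runs strictly shorter than ``max_gap`` frames with
    valid neighbors on both sides are filled by linear interpolation of
    the pixel coordinates (interpolated confidence = mean of the flanking
    confidences); longer runs and runs touching the sequence boundary stay
    invalid.  Returns (filled series, validity mask).
    """
    series = np.array(series, dtype=float, copy=True)
    if series.ndim == 2:
        series = series[:, None, :]
        squeeze = True
    else:
        squeeze = False
    F, m, _ = series.shape
    valid = series[:, :, 2] > conf_threshold
    for j in range(m):
        v = valid[:, j]
        i = 0
        while i < F:
            if v[i]:
                i += 1
                continue
            start = i
            while i < F and not v[i]:
                i += 1
            end = i  # run is [start, end)
            run = end - start
            if start == 0 or end == F or run >= max_gap:
                continue
            left, right = start - 1, end
            t = (np.arange(start, end) - left) / (right - left)
            for d in range(2):
                series[start:end, j, d] = (
                    series[left, j, d] + t * (series[right, j, d] - series[left, j, d])
                )
            series[start:end, j, 2] = 0.5 * (series[left, j, 2] + series[right, j, 2])
            v[start:end] = True
    if squeeze:
        return series[:, 0, :], valid[:, 0]
    return series, valid


def build_distance_specs(
    observations: np.ndarray,
    cams,
    model: ModelDefinition,
    names=None,
    conf_threshold: float = 0.05,
    max_gap: int = 10,
):
    """Triangulate per-frame 3D points from multi-camera 2D observations.

    ``observations`` is (n_frames, n_cameras, n_keypoints, 3) of (x, y,
    confidence) triplets, keypoints ordered as ``names`` (default: the
    model's point registry order).  Each camera's series is thresholded and
    gap-filled, then every keypoint visible in >= 2 cameras is
    reconstructed with the confidence-weighted DLT.  Returns a list of
    distance-mode ObjectiveSpecs (missing points are None).
    """
    observations = np.asarray(observations, dtype=float)
    F, ncam, m, _ = observations.shape
    if names is None:
        names = list(model.point_names)
    filled = np.empty_like(observations)
    valid = np.empty((F, ncam, m), dtype=bool)
    for k in range(ncam):
        filled[:, k], valid[:, k] = preprocess_keypoints(
            observations[:, k], conf_threshold, max_gap
        )
    specs = []
    for f in range(F):
        pts = {}
        for j, name in enumerate(names):
            ks = np.nonzero(valid[f, :, j])[0]
            if len(ks) < 2:
                pts[name] = None
                continue
            obs = [filled[f, k, j, :2] for k in ks]
            confs = [filled[f, k, j, 2] for k in ks]
            try:
                pts[name] = triangulate_wdlt(obs, confs, [cams[k] for k in ks])
            except ValueError:
                pts[name] = None
        specs.append(ObjectiveSpec(mode="distance", points=pts))
    return specs


def build_confidence_specs(
    gaussians: np.ndarray,
    valid: np.ndarray,
    cams,
    model: ModelDefinition,
    names=None,
):
    """Wrap per-frame Gaussian parameters into confidence-mode ObjectiveSpecs.

    ``gaussians`` is (n_frames, n_cameras, n_keypoints, 4) with rows
    (center_x, center_y, amplitude, sigma); ``valid`` masks detected
    entries.  Undetected (keypoint, camera) pairs contribute no term.
    """
    from .heatmap import GaussianModel

    gaussians = np.asarray(gaussians, dtype=float)
    F, ncam, m, _ = gaussians.shape
    if names is None:
        names = list(model.point_names)
    specs = []
    for f in range(F):
        gmap = {}
        for k in range(ncam):
            for j, name in enumerate(names):
                if valid[f, k, j]:
                    cx, cy, A, s = gaussians[f, k, j]
                    gmap[(name, k)] = GaussianModel(np.array([cx, cy]), A, s)
        specs.append(ObjectiveSpec(mode="confidence", gaussians=gmap, cameras=list(cams)))
    return specs
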