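"""Comparison of two kinematics solutions and the associated metrics.

Given two per-frame solution lists (for example a method under test against
ground truth, or the confidence-based against the distance-based pipeline),
computes frame coverage, per-joint 3D Euclidean position errors (reported
in centimeters) and signed per-angle differences wrapped to (-180, 180],
plus descriptive statistics per distribution.  Frames not converged in
either solution are excluded from the error distributions and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .angles import angle_frame, joint_positions
from .model import ModelDefinition

__all__ = [
    "coverage",
    "position_errors",
    "angle_errors",
    "wrap_angle",
    "descriptive_stats",
    "ComparisonReport",
    "compare_solutions",
]


def coverage(solutions) -> float:
    """Percentage of frames with a converged solution (skipped counts as not)."""
    if len(solutions) == 0:
        raise ValueError("empty solution list")
    n_conv = sum(1 for s in solutions if s.converged)
    return 100.0 * n_conv / len(solutions)


def _common_frames(solA, solB):
    if len(solA) != len(solB):
        raise ValueError("solution lists cover different numbers of frames")
    common = [f for f in range(len(solA)) if solA[f].converged and solB[f].converged]
    if not common:
        raise ValueError("no common converged frames")
    return common


def position_errors(solA, solB, model: ModelDefinition, joints=None):
    """Per-joint Euclidean distance samples (meters) over common frames.

    Returns (errors: {joint: array}, n_compared, n_excluded).
    """
    common = _common_frames(solA, solB)
    samples = {}
    for f in common:
        pa = joint_positions(solA[f].Q, model)
        pb = joint_positions(solB[f].Q, model)
        for name in pa:
            if joints is not None and name not in joints:
                continue
            samples.setdefault(name, []).append(float(np.linalg.norm(pa[name] - pb[name])))
    errors = {k: np.asarray(v) for k, v in samples.items()}
    return errors, len(common), len(solA) - len(common)


def wrap_angle(d):
    """Wrap signed angle differences (degrees) to (-180, 180]."""
    d = np.asarray(d, dtype=float)
    return -((-d + 180.0) % 360.0 - 180.0)


def angle_errors(solA, solB, model: ModelDefinition, angles=None):
    """Signed per-angle difference samples (degrees, wrapped) over common frames.

    Returns (errors: {(joint, dof): array}, n_compared, n_excluded).
    """
    common = _common_frames(solA, solB)
    samples = {}
    for f in common:
        aa = angle_frame(solA[f].Q, model)
        ab = angle_frame(solB[f].Q, model)
        for key in aa:
            if angles is not None and key not in angles:
                continue
            samples.setdefault(key, []).append(float(wrap_angle(aa[key] - ab[key])))
    errors = {k: np.asarray(v) for k, v in samples.items()}
    return errors, len(common), len(solA) - len(common)


def descriptive_stats(samples) -> dict:
    """Mean, population std, quartiles (linear interpolation), p99, max."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("no samples")
    return {
        "mean": float(samples.mean()),
        "std": float(samples.std(ddof=0)),
        "p25": float(np.percentile(samples, 25)),
        "median": float(np.percentile(samples, 50)),
        "p75": float(np.percentile(samples, 75)),
        "p99": float(np.percentile(samples, 99)),
        "max": float(samples.max()),
        "n": int(samples.size),
    }


@dataclass
class ComparisonReport:
    """Aggregated comparison between two solution sets."""

    coverage_a: float
    coverage_b: float
    n_frames: int
    n_compared: int
    n_excluded: int
    position_stats_cm: dict = field(default_factory=dict)  # joint -> stats
    angle_stats_deg: dict = field(default_factory=dict)  # "joint/dof" -> stats

    def to_json(self, path=None):
        doc = {
            "coverage_a_pct": self.coverage_a,
            "coverage_b_pct": self.coverage_b,
            "n_frames": self.n_frames,
            "n_compared": self.n_compared,
            "n_excluded": self.n_excluded,
            "position_errors_cm": self.position_stats_cm,
            "angle_errors_deg": self.angle_stats_deg,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


def compare_solutions(solA, solB, model: ModelDefinition, joints=None, angles=None) -> ComparisonReport:
    """Full report: coverage, position errors (cm) and angle errors (deg)."""
    pos, n_cmp, n_exc = position_errors(solA, solB, model, joints)
    ang, _, _ = angle_errors(solA, solB, model, angles)
    return ComparisonReport(
        coverage_a=coverage(solA),
        coverage_b=coverage(solB),
        n_frames=len(solA),
        n_compared=n_cmp,
        n_excluded=n_exc,
        position_stats_cm={k: descriptive_stats(v * 100.0) for k, v in pos.items()},
        angle_stats_deg={f"{j}/{d}": descriptive_stats(v) for (j, d), v in ang.items()},
    )
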