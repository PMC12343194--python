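"""Continuous Gaussian modeling of 2D confidence heatmaps.

Human pose estimation networks emit, per keypoint and camera image, a
discrete confidence map whose argmax is the reported keypoint.  For use
inside a smooth optimizer each map is summarized by an isotropic 2D
Gaussian

    C(x) = A * exp(-|x - center|^2 / (2 sigma^2))

with the center at the maximum-confidence pixel, amplitude A equal to that
maximum, and a single sigma (pixels) estimated from the confidence profile
along the x and y lines through the center within a square window
(60 px by default, clipped — never padded — at image borders).

The raw confidence-weighted standard deviation of pixel positions along a
truncated line systematically underestimates sigma once the window no
longer covers the Gaussian tails.  The default estimator therefore inverts
the windowed statistic: it solves for the sigma whose model-implied
windowed variance matches the observed one, which is exact on noiseless
Gaussian profiles at any sigma.  The uncorrected estimate and the
value-standard-deviation reading (units of confidence, not pixels) are
available as alternative modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GaussianModel",
    "gaussian_confidence",
    "fit_gaussian",
    "render_gaussian",
    "heatmap_difference_stats",
    "fidelity_statistics",
    "save_heatmaps_h5",
    "load_heatmaps_h5",
]

DEFAULT_WINDOW = 60


@dataclass
class GaussianModel:
    """Isotropic 2D Gaussian confidence surrogate for one keypoint/camera/frame."""

    center: np.ndarray  # (x, y) pixels
    amplitude: float  # confidence at the center, in (0, 1]
    sigma: float  # pixels

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def gaussian_confidence(g: GaussianModel, x) -> float:
    """Evaluate the Gaussian confidence surrogate at pixel position x."""
    d2 = float(np.sum((np.asarray(x, dtype=float).reshape(2) - g.center) ** 2))
    return float(g.amplitude * np.exp(-d2 / (2.0 * g.sigma**2)))


def _window_slice(center: int, half: int, size: int):
    """Clipped half-open window [center-half, center+half) within [0, size)."""
    return slice(max(center - half, 0), min(center + half, size))


def _line_sigma(values: np.ndarray, positions: np.ndarray, center: float) -> float:
    """Invert the windowed weighted position variance for sigma.

    ``values`` are confidences sampled at ``positions`` on a line through
    ``center``.  Finds sigma such that a Gaussian centered at ``center``,
    sampled at the same positions, has the same weighted position variance.
    """
    wsum = values.sum()
    if wsum <= 0:
        return 0.0
    mu = (values * positions).sum() / wsum
    var_obs = (values * (positions - mu) ** 2).sum() / wsum
    if var_obs <= 0:
        return 0.0

    def model_var(sigma: float) -> float:
        gw = np.exp(-((positions - center) ** 2) / (2.0 * sigma**2))
        gmu = (gw * positions).sum() / gw.sum()
        return (gw * (positions - gmu) ** 2).sum() / gw.sum()

    lo, hi = 0.05, 1e4
    f_lo = model_var(lo) - var_obs
    f_hi = model_var(hi) - var_obs
    if f_lo >= 0:
        return float(np.sqrt(var_obs))
    if f_hi <= 0:
        # profile flatter than any Gaussian the window can distinguish
        return float(np.sqrt(var_obs))
    return float(brentq(lambda s: model_var(s) - var_obs, lo, hi, xtol=1e-6))


def _raw_line_sigma(values: np.ndarray, positions: np.ndarray) -> float:
    wsum = values.sum()
    if wsum <= 0:
        return 0.0
    mu = (values * positions).sum() / wsum
    return float(np.sqrt((values * (positions - mu) ** 2).sum() / wsum))


def fit_gaussian(hm: np.ndarray, window: int = DEFAULT_WINDOW, mode: str = "position") -> GaussianModel:
    """Fit the four Gaussian parameters to a discrete confidence map.

    The center is the argmax pixel (ties broken toward the smallest row,
    then column — no sub-pixel refinement), the amplitude is the maximum
    value, and sigma is the average of the x-line and y-line estimates
    within the ``window`` x ``window`` neighborhood clipped to the image.

    ``mode='position'`` (default): window-corrected weighted std of pixel
    positions.  ``mode='position_raw'``: uncorrected weighted std.
    ``mode='value'``: std of the confidence values themselves (documented
    alternative reading; yields confidence units, not pixels).
    """
    hm = np.asarray(hm, dtype=float)
    if hm.ndim != 2:
        raise ValueError("heatmap must be a 2D array")
    amp = float(hm.max())
    if amp <= 0:
        raise ValueError("all-zero heatmap: keypoint undetected")
    r, c = np.unravel_index(int(np.argmax(hm)), hm.shape)  # row-major: smallest index wins
    half = window // 2
    rows = _window_slice(r, half, hm.shape[0])
    cols = _window_slice(c, half, hm.shape[1])
    x_vals = hm[r, cols]
    y_vals = hm[rows, c]
    x_pos = np.arange(cols.start, cols.stop, dtype=float)
    y_pos = np.arange(rows.start, rows.stop, dtype=float)
    if mode == "position":
        sx = _line_sigma(x_vals, x_pos, float(c))
        sy = _line_sigma(y_vals, y_pos, float(r))
    elif mode == "position_raw":
        sx = _raw_line_sigma(x_vals, x_pos)
        sy = _raw_line_sigma(y_vals, y_pos)
    elif mode == "value":
        sx = float(np.std(x_vals))
        sy = float(np.std(y_vals))
    else:
        raise ValueError(f"unknown sigma mode {mode!r}")
    sigma = 0.5 * (sx + sy)
    if sigma <= 0:
        sigma = 0.5  # single-pixel blob: narrowest resolvable spread
    return GaussianModel(center=np.array([c, r], dtype=float), amplitude=amp, sigma=sigma)


def render_gaussian(g: GaussianModel, shape) -> np.ndarray:
    """Sample the Gaussian at pixel centers on a (height, width) grid.

    Values are clipped to [0, 1]; the center must lie on the grid for an
    exact render -> fit round trip.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    d2 = (xs - g.center[0]) ** 2 + (ys - g.center[1]) ** 2
    return np.clip(g.amplitude * np.exp(-d2 / (2.0 * g.sigma**2)), 0.0, 1.0)


def heatmap_difference_stats(estimated: np.ndarray, modeled: np.ndarray, window: int = DEFAULT_WINDOW):
    """Absolute differences within the window centered at the estimated argmax.

    Returns (samples, max): the flattened |estimated - modeled| values over
    the clipped window (the per-frame contribution to the pooled difference
    distribution) and their maximum (the contribution to the max-difference
    distribution).
    """
    estimated = np.asarray(estimated, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if estimated.shape != modeled.shape:
        raise ValueError(f"shape mismatch: {estimated.shape} vs {modeled.shape}")
    r, c = np.unravel_index(int(np.argmax(estimated)), estimated.shape)
    half = window // 2
    rows = _window_slice(r, half, estimated.shape[0])
    cols = _window_slice(c, half, estimated.shape[1])
    diff = np.abs(estimated[rows, cols] - modeled[rows, cols]).ravel()
    return diff, float(diff.max())


def fidelity_statistics(samples: np.ndarray) -> dict:
    """Descriptive statistics of a pooled difference distribution."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("no samples")
    return {
        "mean": float(samples.mean()),
        "std": float(samples.std()),
        "p25": float(np.percentile(samples, 25)),
        "p50": float(np.percentile(samples, 50)),
        "p75": float(np.percentile(samples, 75)),
        "p99": float(np.percentile(samples, 99)),
        "max": float(samples.max()),
    }


def save_heatmaps_h5(path, maps: dict) -> None:
    """Store heatmaps as /frame_{i}/cam_{k}/{keypoint} datasets.

    ``maps`` is {(frame, cam, keypoint): 2D array}.
    """
    import h5py

    with h5py.File(path, "w") as f:
        for (frame, cam, kp), hm in maps.items():
            f.create_dataset(
                f"/frame_{frame}/cam_{cam}/{kp}", data=np.asarray(hm, dtype=np.float32)
            )


def load_heatmaps_h5(path) -> dict:
    """Inverse of :func:`save_heatmaps_h5`; returns {(frame, cam, keypoint): array}."""
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for fname, fgrp in f.items():
            frame = int(fname.split("_", 1)[1])
            for cname, cgrp in fgrp.items():
                cam = int(cname.split("_", 1)[1])
                for kp, ds in cgrp.items():
                    out[(frame, cam, kp)] = np.asarray(ds, dtype=float)
    return out
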