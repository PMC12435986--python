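"""2D speed profiles and Kolmogorov-Zurbenko smoothing.

All temporal features operate on the lower-dimensional horizontal (x, y)
speed of the fingertip. The speed series is smoothed with a
Kolmogorov-Zurbenko (KZ) filter — an iterated centered moving average — with
window 2 and 3 iterations by default, whose effective interior kernel is
[1, 3, 3, 1]/8. The jerk series entering the dimensionless-jerk smoothness
index is the second time-derivative of this (smoothed) speed, i.e. the third
derivative of arc-length position; this is the reading under which the index
∫x‴² dt · D³ / max(v)² is exactly dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import DataError, Trajectory

KZ_WINDOW = 2
KZ_ITERATIONS = 3


@dataclass
class SpeedProfile:
    """1D speed time-series of one trial.

    ``v`` is the horizontal speed in mm/s, ``jerk`` its second
    time-derivative (mm/s³) and ``duration_s`` the span D of the recording —
    the three ingredients of the dimensionless jerk index.
    """

    t: np.ndarray
    v: np.ndarray
    jerk: np.ndarray
    duration_s: float
    sampling_hz: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.v.size != self.t.size:
            raise DataError("speed and time series lengths differ")
        if self.duration_s <= 0:
            raise DataError("duration must be positive")


def kz_smooth(series: np.ndarray, window: int = KZ_WINDOW, iterations: int = KZ_ITERATIONS) -> np.ndarray:
    """Kolmogorov-Zurbenko filter: ``iterations``-fold moving average of length ``window``.

    Edges are handled by renormalizing over the part of the kernel that
    overlaps the series, so the output has the input's length and a constant
    series passes through unchanged. For an even window the kernel is
    centered on a half-sample boundary; with window 2 and 3 iterations the
    interior impulse response is [1, 3, 3, 1]/8.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or iterations < 1:
        raise DataError("window and iterations must be >= 1")
    if window > x.size:
        raise DataError(f"window ({window}) exceeds series length ({x.size})")
    if window == 1:
        return x.copy()
    kernel = np.ones(window) / window
    full = np.ones(1)
    for _ in range(iterations):
        full = np.convolve(full, kernel)
    num = np.convolve(x, full, mode="full")
    den = np.convolve(np.ones_like(x), full, mode="full")
    offset = (full.size - 1) // 2
    sl = slice(offset, offset + x.size)
    return num[sl] / den[sl]


def _second_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Second-order-accurate second difference on a uniform grid.

    Central three-point stencil in the interior, one-sided four-point
    stencils at the boundaries (the naive one-sided formulas are only
    first-order accurate there, which visibly biases the jerk integral of a
    short movement whose jerk peaks at its endpoints).
    """
    if v.size < 4:
        raise DataError("need at least 4 samples for the second derivative")
    out = np.empty_like(v)
    out[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / dt**2
    out[0] = (2.0 * v[0] - 5.0 * v[1] + 4.0 * v[2] - v[3]) / dt**2
    out[-1] = (2.0 * v[-1] - 5.0 * v[-2] + 4.0 * v[-3] - v[-4]) / dt**2
    return out


def compute_speed_2d(
    traj: Trajectory,
    smooth: bool = True,
    window: int = KZ_WINDOW,
    iterations: int = KZ_ITERATIONS,
) -> SpeedProfile:
    """Derive the horizontal speed profile of a preprocessed trajectory.

    Velocity comes from central differences of (x, y) (one-sided at the
    endpoints); KZ smoothing is applied to the speed, and the jerk series is
    the second central difference of the (smoothed) speed.
    """
    if traj.n_samples < 5:
        raise DataError("need at least 5 samples to differentiate")
    if traj.missing.any():
        raise DataError("trajectory still contains missing samples; preprocess first")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    v = np.hypot(vx, vy)
    if smooth:
        v = kz_smooth(v, window=window, iterations=iterations)
    jerk = _second_derivative(v, 1.0 / traj.sampling_hz)
    return SpeedProfile(
        t=traj.t.copy(),
        v=v,
        jerk=jerk,
        duration_s=traj.duration_s,
        sampling_hz=traj.sampling_hz,
    )
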