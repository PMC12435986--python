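"""Kinematic features: smoothness, predictability, rhythm, and spatial extent.

Temporal features are computed from the (KZ-smoothed) 2D speed profile:

* **dimensionless jerk** — ∫ x‴(t)² dt · D³ / max(v)², with x‴ the second
  time-derivative of speed; log-transformed because it is long-tailed;
* **sample entropy** — SampEn(m=2, r=0.2·SD, τ=1) of the speed series, the
  negative log conditional probability that patterns similar for m points
  stay similar for m+1 (Chebyshev distance, self-matches excluded);
* **stroke/hold segmentation** — strokes are speed-profile maxima found by a
  prominence/separation peak finder, holds are maximal spans of speed below a
  threshold (15 mm/s by default); **rhythmicity** is the sign-reversed log of
  the sample SD of inter-event intervals, so higher = more isochronous.

Spatial extent is the *maximal covered area*: the rectangle spanned by the
maximal |x| and |y| excursions from the home point (mm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .speed import SpeedProfile, compute_speed_2d
from .trajectory import DataError, Trajectory, TrialRecord

DEFAULT_HOLD_THRESHOLD = 15.0  # speed units (mm/s) — see docs on the unit choice
DEFAULT_PEAK_PROMINENCE_FRAC = 0.05
DEFAULT_PEAK_SEPARATION_S = 0.1


class FeatureNA(Exception):
    """A feature is undefined for this input; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy parameters: pattern length m, delay tau, tolerance r = r_factor·SD."""

    m: int = 2
    tau: int = 1
    r_factor: float = 0.2

    def validate(self) -> None:
        if self.m < 1:
            raise DataError("m must be >= 1")
        if self.tau < 1:
            raise DataError("tau must be >= 1")
        if self.r_factor <= 0:
            raise DataError("r_factor must be positive")


@dataclass
class SegmentationResult:
    """Stroke peaks, hold spans and the inter-event interval series."""

    stroke_peak_indices: np.ndarray
    hold_spans: list[tuple[int, int]]  # [start, end) sample indices
    stroke_intervals_s: np.ndarray
    hold_intervals_s: np.ndarray

    @property
    def n_strokes(self) -> int:
        return int(self.stroke_peak_indices.size)

    @property
    def n_holds(self) -> int:
        return len(self.hold_spans)


def jerkiness(profile: SpeedProfile) -> tuple[float, float]:
    """Dimensionless squared jerk of a speed profile, pre-log and natural log.

    Integrates the squared jerk series over the full recording by the
    trapezoid rule and scales by cubed duration over squared peak speed.
    """
    vmax = float(np.max(profile.v))
    if vmax <= 0:
        raise FeatureNA("max speed is zero; jerk index undefined")
    integral = float(np.trapezoid(profile.jerk**2, profile.t))
    value = integral * profile.duration_s**3 / vmax**2
    if value <= 0:
        # numerically zero jerk (e.g. perfectly uniform motion)
        return value, -math.inf
    return value, math.log(value)


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_templates = x.size - (m - 1) * tau
    idx = np.arange(n_templates)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def sample_entropy(series: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """SampEn(m, r, tau) in nats: −log(A/B) over template pairs.

    ``B`` counts ordered pairs (i ≠ j) of length-m templates within Chebyshev
    distance r; ``A`` the same for length m+1; both use the i-range for which
    the (m+1)-template exists, the standard convention that makes A ⊆ B.
    """
    params.validate()
    x = np.asarray(series, dtype=float)
    m, tau = params.m, params.tau
    if x.size < 10 * (m + 1):
        raise FeatureNA(f"series too short for SampEn (need >= {10 * (m + 1)} samples)")
    sd = float(np.std(x, ddof=1))  # sample SD, matching the usual reference code
    r = params.r_factor * sd
    n_t = x.size - m * tau  # templates for which both lengths are defined
    if n_t < 2:
        raise FeatureNA("too few templates")
    emb_m = _embed(x, m, tau)[:n_t]
    emb_m1 = _embed(x, m + 1, tau)
    # pairwise Chebyshev distances, self-matches excluded
    d_m = np.max(np.abs(emb_m[:, None, :] - emb_m[None, :, :]), axis=2)
    d_m1 = np.max(np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]), axis=2)
    iu = np.triu_indices(n_t, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if b == 0:
        raise FeatureNA("no template matches")
    if a == 0:
        raise FeatureNA("no (m+1)-template matches; entropy infinite")
    return float(-math.log(a / b))


def segment_strokes_holds(
    profile: SpeedProfile,
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    peak_min_prominence: float | None = None,
    peak_min_separation_s: float = DEFAULT_PEAK_SEPARATION_S,
) -> SegmentationResult:
    """Segment a speed profile into strokes (speed maxima) and holds.

    Peak prominence defaults to 5% of the profile's peak speed; peaks closer
    than ``peak_min_separation_s`` are merged by the peak finder. Stroke
    intervals are between successive peaks, hold intervals between successive
    hold onsets.
    """
    v = profile.v
    vmax = float(np.max(v)) if v.size else 0.0
    if peak_min_prominence is None:
        peak_min_prominence = DEFAULT_PEAK_PROMINENCE_FRAC * vmax
    distance = max(int(round(peak_min_separation_s * profile.sampling_hz)), 1)
    if vmax > 0:
        peaks, _ = find_peaks(v, prominence=peak_min_prominence, distance=distance)
    else:
        peaks = np.array([], dtype=int)

    below = v < hold_threshold
    spans: list[tuple[int, int]] = []
    edges = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        spans.append((int(s), int(e)))

    stroke_intervals = np.diff(profile.t[peaks]) if peaks.size >= 2 else np.array([])
    onsets = np.array([s for s, _ in spans], dtype=int)
    hold_intervals = np.diff(profile.t[onsets]) if onsets.size >= 2 else np.array([])
    return SegmentationResult(
        stroke_peak_indices=peaks,
        hold_spans=spans,
        stroke_intervals_s=stroke_intervals,
        hold_intervals_s=hold_intervals,
    )


def rhythmicity(
    intervals_s: np.ndarray, eps_s: float = 1.0 / 120.0
) -> tuple[float, bool]:
    """Sign-reversed log sample SD of inter-event intervals.

    Returns ``(value, clamped)``; a zero SD (perfect isochrony) is clamped at
    ``eps_s`` (one sample period by default) and flagged.
    """
    iv = np.asarray(intervals_s, dtype=float)
    if iv.size < 2:
        raise FeatureNA("fewer than 2 intervals; rhythmicity undefined")
    sd = float(np.std(iv, ddof=1))
    if sd <= 1e-12:  # exact isochrony up to floating point
        return -math.log(eps_s), True
    return -math.log(sd), False


def max_covered_area(traj: Trajectory) -> float:
    """Rectangle area (mm²) under the maximal |x| and |y| excursions from home."""
    xy = traj.xy_home_centered()[~traj.missing]
    if xy.shape[0] == 0:
        return float("nan")
    return float(np.max(np.abs(xy[:, 0])) * np.max(np.abs(xy[:, 1])))


def descriptive_features(profile: SpeedProfile, traj: Trajectory) -> dict:
    """Peak speed, mean |acceleration|, duration and maximal height above home."""
    accel = np.gradient(profile.v, profile.t)
    return {
        "peak_speed_mm_s": float(np.max(profile.v)),
        "mean_accel_mm_s2": float(np.mean(np.abs(accel))),
        "duration_s": float(profile.duration_s),
        "height_mm": float(np.max(traj.z[~traj.missing] - traj.home_point[2])),
    }


def compute_features(
    trials: list[TrialRecord],
    hold_threshold: float = DEFAULT_HOLD_THRESHOLD,
    entropy_params: EntropyParams = EntropyParams(),
    peak_min_prominence: float | None = None,
    peak_min_separation_s: float = DEFAULT_PEAK_SEPARATION_S,
) -> pd.DataFrame:
    """Per-trial feature table (wide), one row per trial.

    Undefined features become NaN with the reason recorded in
    ``na_reasons`` (semicolon-joined).
    """
    rows = []
    for tr in trials:
        profile = compute_speed_2d(tr.trajectory)
        row: dict = dict(tr.labels())
        reasons = []

        def attempt(name, fn):
            try:
                row[name] = fn()
            except FeatureNA as na:
                row[name] = np.nan
                reasons.append(f"{name}: {na.reason}")

        attempt("log_jerkiness", lambda: jerkiness(profile)[1])
        attempt("sample_entropy", lambda: sample_entropy(profile.v, entropy_params))
        seg = segment_strokes_holds(
            profile,
            hold_threshold=hold_threshold,
            peak_min_prominence=peak_min_prominence,
            peak_min_separation_s=peak_min_separation_s,
        )
        row["n_strokes"] = seg.n_strokes
        row["n_holds"] = seg.n_holds
        attempt("rhythm_strokes", lambda: rhythmicity(seg.stroke_intervals_s)[0])
        attempt("rhythm_holds", lambda: rhythmicity(seg.hold_intervals_s)[0])
        row["max_area_mm2"] = max_covered_area(tr.trajectory)
        row.update(descriptive_features(profile, tr.trajectory))
        row["na_reasons"] = "; ".join(reasons)
        rows.append(row)
    return pd.DataFrame(rows)


FEATURE_COLUMNS = [
    "log_jerkiness",
    "sample_entropy",
    "rhythm_strokes",
    "rhythm_holds",
    "max_area_mm2",
    "peak_speed_mm_s",
    "mean_accel_mm_s2",
    "duration_s",
    "height_mm",
]


def features_long(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format variant: one row per trial × feature."""
    label_cols = [c for c in table.columns if c not in FEATURE_COLUMNS + ["na_reasons", "n_strokes", "n_holds"]]
    return table.melt(
        id_vars=label_cols,
        value_vars=[c for c in FEATURE_COLUMNS if c in table.columns],
        var_name="feature",
        value_name="value",
    )
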