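"""Trajectory preprocessing: zero-lag low-pass resampling and exclusion rules.

The pipeline mirrors standard motion-capture practice for hand kinematics:

1. smooth each coordinate with a fourth-order zero-lag (forward-backward)
   Butterworth low-pass filter at the source rate and resample to 120 Hz;
2. drop trials containing any run of more than 12 successive missing samples
   (100 ms at 120 Hz);
3. within each participant, drop trials whose maximal horizontal displacement
   from the home point falls below mean − 3 SD of that participant's
   distribution — and drop the same trial's counterpart in the other
   condition, so retained counts stay balanced across conditions.

The Butterworth cutoff frequency is a mandatory, reported choice (default
10 Hz, conventional for gross hand movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .trajectory import (
    ConfigurationError,
    DataError,
    IntegrityError,
    Trajectory,
    TrialRecord,
)

DEFAULT_TARGET_HZ = 120.0
DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_MAX_GAP_SAMPLES = 12
DEFAULT_K_SD = 3.0


@dataclass
class ExclusionReport:
    """Bookkeeping for the exclusion cascade.

    Counts are keyed by ``"group/condition"``; ``reasons`` lists
    ``(trial uid, reason)`` for every removed trial.
    """

    n_input: dict = field(default_factory=dict)
    n_gap_excluded: int = 0
    n_displacement_excluded: int = 0
    n_pair_propagated: int = 0
    n_retained: dict = field(default_factory=dict)
    reasons: list = field(default_factory=list)

    @staticmethod
    def _count(trials) -> dict:
        out: dict = {}
        for tr in trials:
            key = f"{tr.group}/{tr.condition}"
            out[key] = out.get(key, 0) + 1
        return out

    def merge(self, other: "ExclusionReport") -> "ExclusionReport":
        merged = ExclusionReport(
            n_input=dict(self.n_input) or dict(other.n_input),
            n_gap_excluded=self.n_gap_excluded + other.n_gap_excluded,
            n_displacement_excluded=self.n_displacement_excluded
            + other.n_displacement_excluded,
            n_pair_propagated=self.n_pair_propagated + other.n_pair_propagated,
            n_retained=dict(other.n_retained) or dict(self.n_retained),
            reasons=self.reasons + other.reasons,
        )
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_gap_excluded": self.n_gap_excluded,
            "n_displacement_excluded": self.n_displacement_excluded,
            "n_pair_propagated": self.n_pair_propagated,
            "n_retained": self.n_retained,
            "reasons": [list(r) for r in self.reasons],
        }


def missing_run_lengths(missing: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean mask."""
    m = np.asarray(missing, dtype=bool)
    if m.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list((ends - starts).astype(int))


def resample_filter(
    traj: Trajectory,
    target_hz: float = DEFAULT_TARGET_HZ,
    order: int = 4,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> Trajectory:
    """Zero-lag Butterworth low-pass filter and resample to ``target_hz``.

    The filter runs at the source rate (forward and backward, so the overall
    order is ``order`` with no phase shift), then the signal is decimated —
    every k-th sample when the rate ratio is an integer, linear interpolation
    onto the uniform target grid otherwise. Leading/trailing missing samples
    are trimmed; interior missing runs are linearly interpolated before
    filtering and re-flagged in the output so the gap-exclusion rule can
    still see them.
    """
    if order < 2 or order % 2 != 0:
        raise ConfigurationError("order must be an even integer >= 2")
    if cutoff_hz >= target_hz / 2.0:
        raise ConfigurationError(
            f"cutoff_hz ({cutoff_hz}) must be below the target Nyquist ({target_hz / 2})"
        )
    finite = ~traj.missing
    if finite.sum() < 8 * order:
        raise DataError(f"need at least {8 * order} finite samples, got {int(finite.sum())}")

    first, last = np.flatnonzero(finite)[[0, -1]]
    sl = slice(first, last + 1)
    t = traj.t[sl]
    miss = traj.missing[sl].copy()

    channels = []
    for ch in (traj.x, traj.y, traj.z):
        c = ch[sl].astype(float)
        if miss.any():
            c[miss] = np.interp(t[miss], t[~miss], c[~miss])
        if np.any(~np.isfinite(c)):
            raise DataError("non-finite samples outside flagged missing runs")
        b, a = butter(order // 2, cutoff_hz / (traj.sampling_hz / 2.0))
        # Gustafsson edge handling keeps the zero-lag filter exactly
        # time-reversal symmetric (default padding is not)
        channels.append(filtfilt(b, a, c, method="gust"))

    ratio = traj.sampling_hz / target_hz
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
        k = int(round(ratio))
        t_out = t[::k]
        out_ch = [c[::k] for c in channels]
        # an output sample is flagged when any source sample in its window was
        n = t_out.size
        pad = (-miss.size) % k
        m = np.concatenate((miss, np.zeros(pad, dtype=bool))).reshape(-1, k)
        miss_out = m.any(axis=1)[:n]
    else:
        t_out = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * target_hz)) + 1) / target_hz
        out_ch = [np.interp(t_out, t, c) for c in channels]
        edges = np.concatenate((t_out - 0.5 / target_hz, [t_out[-1] + 0.5 / target_hz]))
        counts, _ = np.histogram(t[miss], bins=edges)
        miss_out = counts > 0

    return Trajectory(
        t=t_out,
        x=out_ch[0],
        y=out_ch[1],
        z=out_ch[2],
        missing=miss_out,
        sampling_hz=target_hz,
        home_point=tuple(traj.home_point),
    )


def exclude_gap_trials(
    trials: list[TrialRecord], max_gap_samples: int = DEFAULT_MAX_GAP_SAMPLES
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Drop trials with any missing run strictly longer than ``max_gap_samples``.

    Runs are counted on the trial's own (post-resampling) grid; at 120 Hz the
    default of 12 samples corresponds to 100 ms of recording.
    """
    report = ExclusionReport(n_input=ExclusionReport._count(trials))
    retained = []
    for tr in trials:
        runs = missing_run_lengths(tr.trajectory.missing)
        worst = max(runs, default=0)
        if worst > max_gap_samples:
            report.n_gap_excluded += 1
            report.reasons.append((tr.uid, f"missing run of {worst} samples"))
        else:
            retained.append(tr)
    report.n_retained = ExclusionReport._count(retained)
    return retained, report


def exclude_displacement_outliers(
    trials: list[TrialRecord], k_sd: float = DEFAULT_K_SD
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Drop low-displacement outlier trials per participant, with paired removal.

    For each participant the distribution of maximal horizontal displacement
    from home is formed over all of that participant's trials (conditions and
    sessions pooled; see docs), and trials strictly below mean − ``k_sd``·SD
    (sample SD) are removed. Each removed trial's counterpart in the other
    condition is then removed too, which keeps the two conditions balanced at
    the price of doubling the exclusion rate.
    """
    report = ExclusionReport(n_input=ExclusionReport._count(trials))
    by_participant: dict = {}
    for i, tr in enumerate(trials):
        by_participant.setdefault(tr.participant_id, []).append(i)

    outliers: set[int] = set()
    for pid, idxs in by_participant.items():
        disp = np.array([trials[i].trajectory.max_displacement_mm() for i in idxs])
        if len(idxs) < 2:
            continue
        thresh = disp.mean() - k_sd * disp.std(ddof=1)
        for i, d in zip(idxs, disp):
            if d < thresh:
                outliers.add(i)
                report.reasons.append(
                    (trials[i].uid, f"max displacement {d:.2f} mm < {thresh:.2f} mm")
                )
    report.n_displacement_excluded = len(outliers)

    # paired removal: drop the counterpart (same labels, other condition)
    by_pair: dict = {}
    for i, tr in enumerate(trials):
        by_pair.setdefault(tr.pair_key, {})[tr.condition] = i
    propagated: set[int] = set()
    for i in outliers:
        tr = trials[i]
        other = "communicative" if tr.condition == "non_communicative" else "non_communicative"
        j = by_pair.get(tr.pair_key, {}).get(other)
        if j is None:
            report.reasons.append((tr.uid, "unpaired trial at propagation; removed alone"))
        elif j not in outliers:
            propagated.add(j)
            report.reasons.append((trials[j].uid, f"counterpart of excluded {tr.uid}"))
    # balance guarantee: any trial without a counterpart (e.g. lost to the
    # gap rule upstream) is removed too, so condition counts stay equal
    unpaired: set[int] = set()
    for i, tr in enumerate(trials):
        if len(by_pair.get(tr.pair_key, {})) < 2 and i not in outliers:
            unpaired.add(i)
            report.reasons.append((tr.uid, "unpaired trial; counterpart absent"))
    report.n_pair_propagated = len(propagated) + len(unpaired)

    removed = outliers | propagated | unpaired
    retained = [tr for i, tr in enumerate(trials) if i not in removed]
    report.n_retained = ExclusionReport._count(retained)
    return retained, report


def preprocess_trials(
    trials: list[TrialRecord],
    target_hz: float = DEFAULT_TARGET_HZ,
    order: int = 4,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    max_gap_samples: int = DEFAULT_MAX_GAP_SAMPLES,
    k_sd: float = DEFAULT_K_SD,
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Full preprocessing cascade: resample/filter, gap rule, outlier rule."""
    resampled = [
        tr.with_trajectory(resample_filter(tr.trajectory, target_hz, order, cutoff_hz))
        for tr in trials
    ]
    kept, rep_gap = exclude_gap_trials(resampled, max_gap_samples)
    kept, rep_disp = exclude_displacement_outliers(kept, k_sd)
    return kept, rep_gap.merge(rep_disp)
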