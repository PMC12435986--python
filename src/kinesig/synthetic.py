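"""Synthetic mocap-like trajectory generation.

The generator emulates the structure of tabletop hand movements recorded in a
paired design: each *item* is performed once as a re-enactment
(non-communicative) and once as a description (communicative). A trajectory
is a chain of planar minimum-jerk submovements ("strokes") separated by flat
zero-velocity spans ("holds"), with additive Gaussian sensor noise. The
communicative member of a pair shares the spatial path of its partner but may
have its whole stroke/hold timeline stretched or compressed, a different
inter-stroke interval variability, and different noise — the three knobs that
drive the temporal features downstream (warping cost, rhythmicity, jerkiness,
entropy).

Cohort generation adds log-normal multiplicative participant- and item-level
perturbations to durations and amplitudes, mirroring the random-effect
structure the mixed models estimate.

All randomness flows through ``numpy.random.SeedSequence`` children of a
single named seed, so every generator is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import ConfigurationError, DataError, IntegrityError, Trajectory, TrialRecord

# Flat rest spans before the first and after the last stroke, as a fraction of
# the mean inter-stroke interval (scaled together with the rest of the
# timeline by the pair stretch factor).
LEAD_TAIL_FRACTION = 0.5
# Minimum gap left between consecutive strokes when sampled intervals collide.
MIN_GAP_S = 0.02


@dataclass(frozen=True)
class StrokeChainConfig:
    """Parameters of one stroke-chain trajectory.

    Defaults are chosen to resemble a few-second tabletop movement: four
    ~35 cm/s strokes of 120 mm amplitude, 0.35 s each, one stroke roughly
    every 0.7 s, recorded at 480 Hz with sub-millimeter sensor noise.
    """

    n_strokes: int = 4
    stroke_amplitude_mm: float = 120.0
    stroke_duration_s: float = 0.35
    interstroke_interval_mean_s: float = 0.7
    interstroke_interval_sd_s: float = 0.08
    hold_fraction: float = 1.0
    noise_sd_mm: float = 0.4
    sampling_hz: float = 480.0
    seed: int = 0
    height_mm: float = 20.0

    def validate(self) -> None:
        if self.n_strokes < 1:
            raise ConfigurationError("n_strokes must be >= 1")
        if self.stroke_amplitude_mm <= 0:
            raise ConfigurationError("stroke_amplitude_mm must be positive")
        if self.stroke_duration_s <= 0:
            raise ConfigurationError("stroke_duration_s must be positive")
        if self.interstroke_interval_mean_s <= 0:
            raise ConfigurationError("interstroke_interval_mean_s must be positive")
        if self.interstroke_interval_sd_s < 0:
            raise ConfigurationError("interstroke_interval_sd_s must be nonnegative")
        if not 0.0 <= self.hold_fraction <= 1.0:
            raise ConfigurationError("hold_fraction must lie in [0, 1]")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be nonnegative")
        if self.sampling_hz <= 0:
            raise ConfigurationError("sampling_hz must be positive")
        if self.stroke_duration_s * self.sampling_hz < 8:
            raise ConfigurationError(
                "sampling_hz too low to resolve stroke_duration_s (need >= 8 samples per stroke)"
            )


@dataclass(frozen=True)
class PairConfig:
    """One non-communicative/communicative trial pair.

    ``stretch_factor`` is the ratio of communicative to non-communicative
    duration; the deltas are added to the interval SD and the noise SD of the
    communicative member (and may be negative, down to zero).
    """

    base: StrokeChainConfig = field(default_factory=StrokeChainConfig)
    stretch_factor: float = 1.0
    delta_interval_sd_s: float = 0.0
    delta_noise_sd_mm: float = 0.0

    def validate(self) -> None:
        self.base.validate()
        if self.stretch_factor <= 0:
            raise ConfigurationError("stretch_factor must be positive")
        if self.base.interstroke_interval_sd_s + self.delta_interval_sd_s < 0:
            raise ConfigurationError(
                "delta_interval_sd_s drives the communicative interval SD negative"
            )
        if self.base.noise_sd_mm + self.delta_noise_sd_mm < 0:
            raise ConfigurationError(
                "delta_noise_sd_mm drives the communicative noise SD negative"
            )


@dataclass(frozen=True)
class CohortConfig:
    """A two-group cohort with crossed participant and item random effects."""

    n_speakers: int = 8
    n_signers: int = 8
    n_items: int = 4
    trials_per_item: int = 1
    speaker_pair_profile: PairConfig = field(default_factory=PairConfig)
    signer_pair_profile: PairConfig = field(default_factory=PairConfig)
    between_participant_sd: float = 0.1
    between_item_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_speakers", "n_signers", "n_items", "trials_per_item"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.between_participant_sd < 0:
            raise ConfigurationError("between_participant_sd must be nonnegative")
        if self.between_item_sd < 0:
            raise ConfigurationError("between_item_sd must be nonnegative")
        self.speaker_pair_profile.validate()
        self.signer_pair_profile.validate()


def _minimum_jerk_s(tau: np.ndarray) -> np.ndarray:
    """Quintic minimum-jerk displacement profile on tau in [0, 1]."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _geometry(config: StrokeChainConfig, rng: np.random.Generator) -> np.ndarray:
    """Planar stroke endpoints starting at the origin.

    Headings turn by 40–140 degrees with random sign between strokes; for
    chains of two or more strokes the final stroke returns to the origin so
    the hand ends at the home point.
    """
    n = config.n_strokes
    heading = rng.uniform(0.0, 2.0 * math.pi)
    pts = [np.zeros(2)]
    for _ in range(n):
        step = config.stroke_amplitude_mm * np.array(
            [math.cos(heading), math.sin(heading)]
        )
        pts.append(pts[-1] + step)
        turn = rng.uniform(math.radians(40.0), math.radians(140.0))
        heading += turn * (1.0 if rng.random() < 0.5 else -1.0)
    pts = np.array(pts)
    if n >= 2:
        pts[-1] = np.zeros(2)  # last stroke returns home
    return pts


def _timeline(
    config: StrokeChainConfig, z: np.ndarray, stretch: float, interval_sd: float
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Lead hold, stroke durations, inter-stroke holds and tail hold (seconds).

    ``z`` holds the standard-normal interval draws so that a pair can share
    them across conditions; the whole timeline scales by ``stretch``.
    """
    n = config.n_strokes
    d = config.stroke_duration_s
    intervals = config.interstroke_interval_mean_s + interval_sd * z
    gaps = np.maximum(intervals - d, MIN_GAP_S)
    hf = config.hold_fraction
    holds = hf * gaps
    extra = (1.0 - hf) * gaps  # split onto the two adjacent strokes
    durations = np.full(n, d)
    if n >= 2:
        durations[:-1] += extra / 2.0
        durations[1:] += extra / 2.0
    lead = tail = LEAD_TAIL_FRACTION * config.interstroke_interval_mean_s
    return lead * stretch, durations * stretch, holds * stretch, tail * stretch


def _render(
    config: StrokeChainConfig,
    pts: np.ndarray,
    lead: float,
    durations: np.ndarray,
    holds: np.ndarray,
    tail: float,
    noise_sd: float,
    rng_noise: np.random.Generator,
) -> Trajectory:
    """Sample the piecewise minimum-jerk chain on a uniform time grid."""
    n = config.n_strokes
    hz = config.sampling_hz
    # segment boundaries: lead | stroke1 | hold1 | ... | strokeN | tail
    seg_len = [lead]
    for k in range(n):
        seg_len.append(durations[k])
        if k < n - 1:
            seg_len.append(holds[k])
    seg_len.append(tail)
    edges = np.concatenate(([0.0], np.cumsum(seg_len)))
    total = edges[-1]
    t = np.arange(int(math.floor(total * hz)) + 1) / hz
    seg_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(seg_len) - 1)

    xy = np.empty((t.size, 2))
    for s, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mask = seg_idx == s
        if not mask.any():
            continue
        if s == 0:  # lead hold
            xy[mask] = pts[0]
        elif s == len(seg_len) - 1:  # tail hold
            xy[mask] = pts[n]
        elif (s - 1) % 2 == 0:  # stroke k
            k = (s - 1) // 2
            tau = (t[mask] - lo) / (hi - lo)
            prof = _minimum_jerk_s(np.clip(tau, 0.0, 1.0))
            xy[mask] = pts[k] + np.outer(prof, pts[k + 1] - pts[k])
        else:  # hold after stroke k
            k = (s - 1) // 2
            xy[mask] = pts[k + 1]

    if noise_sd > 0:
        xy = xy + rng_noise.normal(0.0, noise_sd, size=xy.shape)
    home = (0.0, 0.0, config.height_mm)
    return Trajectory(
        t=t,
        x=xy[:, 0] + home[0],
        y=xy[:, 1] + home[1],
        z=np.full(t.size, config.height_mm),
        missing=np.zeros(t.size, dtype=bool),
        sampling_hz=hz,
        home_point=home,
    )


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def gen_trajectory(config: StrokeChainConfig) -> Trajectory:
    """Generate one stroke-chain trajectory (no missing samples)."""
    config.validate()
    rng_geom, rng_time, rng_noise, _ = _streams(config.seed)
    pts = _geometry(config, rng_geom)
    z = rng_time.standard_normal(max(config.n_strokes - 1, 0))
    lead, durs, holds, tail = _timeline(
        config, z, stretch=1.0, interval_sd=config.interstroke_interval_sd_s
    )
    return _render(config, pts, lead, durs, holds, tail, config.noise_sd_mm, rng_noise)


def gen_pair(
    config: PairConfig,
    participant_id: str = "P01",
    group: str = "speaker",
    item_id: str = "item01",
    session: int = 1,
    trial_index: int = 0,
) -> tuple[TrialRecord, TrialRecord]:
    """Generate a (non-communicative, communicative) trial pair.

    Both members share the spatial path and the standard-normal interval
    draws; the communicative member's timeline is scaled by
    ``stretch_factor`` and uses the delta-adjusted interval/noise SDs, so with
    zero deltas and zero noise a stretch of 1 reproduces the partner exactly.
    """
    config.validate()
    base = config.base
    rng_geom, rng_time, rng_noise_nc, rng_noise_c = _streams(base.seed)
    pts = _geometry(base, rng_geom)
    z = rng_time.standard_normal(max(base.n_strokes - 1, 0))

    lead, durs, holds, tail = _timeline(
        base, z, stretch=1.0, interval_sd=base.interstroke_interval_sd_s
    )
    traj_nc = _render(base, pts, lead, durs, holds, tail, base.noise_sd_mm, rng_noise_nc)

    sd_c = base.interstroke_interval_sd_s + config.delta_interval_sd_s
    noise_c = base.noise_sd_mm + config.delta_noise_sd_mm
    lead, durs, holds, tail = _timeline(
        base, z, stretch=config.stretch_factor, interval_sd=sd_c
    )
    traj_c = _render(base, pts, lead, durs, holds, tail, noise_c, rng_noise_c)

    common = dict(
        participant_id=participant_id,
        group=group,
        item_id=item_id,
        session=session,
        trial_index=trial_index,
    )
    return (
        TrialRecord(condition="non_communicative", trajectory=traj_nc, **common),
        TrialRecord(condition="communicative", trajectory=traj_c, **common),
    )


def gen_cohort(config: CohortConfig) -> list[TrialRecord]:
    """Generate a fully labeled cohort of trial pairs.

    Participant- and item-level multiplicative log-normal perturbations are
    drawn once per unit and applied to stroke/interval durations and stroke
    amplitudes of every trial of that unit.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_part, rng_item, rng_seed = (np.random.default_rng(c) for c in root.spawn(3))

    participants = [(f"S{i + 1:02d}", "speaker") for i in range(config.n_speakers)]
    participants += [(f"G{i + 1:02d}", "signer") for i in range(config.n_signers)]
    items = [f"item{j + 1:02d}" for j in range(config.n_items)]

    p_eff = {
        pid: np.exp(rng_part.normal(0.0, config.between_participant_sd, size=2))
        for pid, _ in participants
    }
    i_eff = {
        iid: np.exp(rng_item.normal(0.0, config.between_item_sd, size=2))
        for iid in items
    }

    records: list[TrialRecord] = []
    for pid, grp in participants:
        profile = (
            config.speaker_pair_profile if grp == "speaker" else config.signer_pair_profile
        )
        dur_p, amp_p = p_eff[pid]
        for iid in items:
            dur_i, amp_i = i_eff[iid]
            for trial in range(config.trials_per_item):
                base = replace(
                    profile.base,
                    stroke_duration_s=profile.base.stroke_duration_s * dur_p * dur_i,
                    interstroke_interval_mean_s=(
                        profile.base.interstroke_interval_mean_s * dur_p * dur_i
                    ),
                    stroke_amplitude_mm=profile.base.stroke_amplitude_mm * amp_p * amp_i,
                    seed=int(rng_seed.integers(2**31)),
                )
                pair_cfg = replace(profile, base=base)
                nc, c = gen_pair(
                    pair_cfg,
                    participant_id=pid,
                    group=grp,
                    item_id=iid,
                    trial_index=trial,
                )
                records.extend((nc, c))
    return records


def inject_artifacts(
    trials: list[TrialRecord],
    gap_run_lengths: list[int] = (),
    outlier_trial_ids: list[str] = (),
    outlier_scale: float = 0.1,
    gap_trial_ids: list[str] | None = None,
) -> list[TrialRecord]:
    """Return modified copies with missing-sample runs and displacement outliers.

    The k-th gap run is punched into the middle of the k-th trial of the
    collection unless ``gap_trial_ids`` names the targets explicitly. Outlier
    trials have their horizontal displacement about the home point rescaled
    by ``outlier_scale``. Originals are left untouched; no sample outside the
    specified runs/trials changes.
    """
    if not 0.0 < outlier_scale < 1.0 or not outlier_trial_ids:
        if outlier_trial_ids and not 0.0 < outlier_scale < 1.0:
            raise ConfigurationError("outlier_scale must lie in (0, 1)")
    by_uid = {tr.uid: i for i, tr in enumerate(trials)}
    out = [tr.with_trajectory(tr.trajectory.copy()) for tr in trials]

    if gap_trial_ids is None:
        gap_targets = list(range(len(gap_run_lengths)))
        if len(gap_run_lengths) > len(trials):
            raise DataError("more gap runs than trials")
    else:
        if len(gap_trial_ids) != len(gap_run_lengths):
            raise ConfigurationError("gap_trial_ids must match gap_run_lengths in length")
        try:
            gap_targets = [by_uid[u] for u in gap_trial_ids]
        except KeyError as err:
            raise IntegrityError(f"gap trial id not found: {err.args[0]}") from None

    for idx, run in zip(gap_targets, gap_run_lengths):
        traj = out[idx].trajectory
        if run > traj.n_samples:
            raise DataError(
                f"gap run of {run} samples does not fit in trial {out[idx].uid}"
            )
        start = (traj.n_samples - run) // 2
        sl = slice(start, start + run)
        traj.missing[sl] = True
        traj.x[sl] = np.nan
        traj.y[sl] = np.nan
        traj.z[sl] = np.nan

    for uid in outlier_trial_ids:
        if uid not in by_uid:
            raise IntegrityError(f"outlier trial id not found: {uid}")
        traj = out[by_uid[uid]].trajectory
        x0, y0, _ = traj.home_point
        traj.x = x0 + outlier_scale * (traj.x - x0)
        traj.y = y0 + outlier_scale * (traj.y - y0)

    return out
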