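"""Preprocessing: zero-lag filtering, resampling, exclusion rules, tidy CSV I/O."""

import numpy as np
import pytest

from kinesig.io import read_trials, write_trials
from kinesig.preprocess import (
    exclude_displacement_outliers,
    exclude_gap_trials,
    missing_run_lengths,
    preprocess_trials,
    resample_filter,
)
from kinesig.synthetic import CohortConfig, gen_cohort, inject_artifacts
from kinesig.trajectory import ConfigurationError, DataError, Trajectory

from conftest import make_record, min_jerk_trajectory, square_path_trajectory


def flat_trajectory(hz=480.0, duration=2.0, value=7.5):
    n = int(duration * hz)
    t = np.arange(n) / hz
    c = np.full(n, value)
    return Trajectory(t=t, x=c, y=c, z=c, missing=np.zeros(n, bool), sampling_hz=hz)


def test_constant_position_passes_through_dc():
    out = resample_filter(flat_trajectory(), target_hz=120.0, cutoff_hz=10.0)
    assert out.sampling_hz == 120.0
    assert out.n_samples == 240
    np.testing.assert_allclose(out.x, 7.5, atol=1e-9)


def test_stopband_component_attenuated():
    hz, dur = 480.0, 4.0
    t = np.arange(int(hz * dur)) / hz
    x = 10.0 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 50.0 * t)
    traj = Trajectory(t=t, x=x, y=np.zeros_like(t), z=np.zeros_like(t),
                      missing=np.zeros(t.size, bool), sampling_hz=hz)
    out = resample_filter(traj, target_hz=120.0, cutoff_hz=10.0)
    # 50 Hz is above the 120 Hz output Nyquist; check it died before decimation
    spec_in = np.abs(np.fft.rfft(x))
    f_in = np.fft.rfftfreq(x.size, 1 / hz)
    b, a = __import__("scipy.signal", fromlist=["butter"]).butter(2, 10.0 / (hz / 2))
    from scipy.signal import filtfilt

    filtered = filtfilt(b, a, x)
    spec_f = np.abs(np.fft.rfft(filtered))
    amp50_in = spec_in[np.argmin(np.abs(f_in - 50.0))]
    amp50_out = spec_f[np.argmin(np.abs(f_in - 50.0))]
    assert amp50_out < 0.01 * amp50_in
    # the passband 1 Hz component survives in the resampled output
    f_out = np.fft.rfftfreq(out.n_samples, 1 / 120.0)
    spec_out = np.abs(np.fft.rfft(out.x))
    amp1 = 2 * spec_out[np.argmin(np.abs(f_out - 1.0))] / out.n_samples
    assert amp1 == pytest.approx(10.0, rel=0.05)


def test_zero_lag_time_reversal_symmetry():
    rng = np.random.default_rng(0)
    hz = 480.0
    t = np.arange(2400) / hz
    x = np.cumsum(rng.normal(size=t.size))
    traj = Trajectory(t=t, x=x, y=x[::-1].copy(), z=np.zeros_like(t),
                      missing=np.zeros(t.size, bool), sampling_hz=hz)
    fwd = resample_filter(traj, target_hz=480.0, cutoff_hz=10.0)
    rev_in = Trajectory(t=t, x=x[::-1].copy(), y=x.copy(), z=np.zeros_like(t),
                        missing=np.zeros(t.size, bool), sampling_hz=hz)
    rev = resample_filter(rev_in, target_hz=480.0, cutoff_hz=10.0)
    np.testing.assert_allclose(fwd.x, rev.x[::-1], atol=1e-9)


def test_cutoff_above_nyquist_rejected():
    with pytest.raises(ConfigurationError):
        resample_filter(flat_trajectory(), target_hz=120.0, cutoff_hz=80.0)


def test_all_missing_channel_rejected():
    traj = flat_trajectory()
    traj.missing[:] = True
    traj.x[:] = np.nan
    with pytest.raises(DataError):
        resample_filter(traj)


def test_resampling_conserves_displacement_of_smooth_path():
    traj = min_jerk_trajectory(amplitude_mm=80.0, duration_s=2.0, hz=480.0)
    out = resample_filter(traj, target_hz=120.0, cutoff_hz=10.0)
    d_in = np.sum(np.abs(np.diff(traj.x)))
    d_out = np.sum(np.abs(np.diff(out.x)))
    assert d_out == pytest.approx(d_in, rel=1e-3)


def test_missing_run_lengths_oracle():
    m = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1], dtype=bool)
    assert missing_run_lengths(m) == [2, 1, 3]
    assert missing_run_lengths(np.zeros(5, bool)) == []


class TestGapExclusion:
    def _trials(self, run_lengths):
        cfg = CohortConfig(n_speakers=1, n_signers=0 or 1, n_items=len(run_lengths), seed=8)
        trials = gen_cohort(CohortConfig(n_speakers=1, n_signers=1,
                                         n_items=max(len(run_lengths), 1), seed=8))
        return inject_artifacts(trials, gap_run_lengths=run_lengths)

    def test_run_of_13_excluded_12_retained(self):
        trials = self._trials([13, 12])
        kept, report = exclude_gap_trials(trials, max_gap_samples=12)
        kept_uids = {tr.uid for tr in kept}
        assert trials[0].uid not in kept_uids  # 13-sample run: excluded
        assert trials[1].uid in kept_uids  # 12-sample run: strict boundary, retained
        assert report.n_gap_excluded == 1

    def test_two_short_runs_do_not_sum(self):
        trials = gen_cohort(CohortConfig(n_speakers=1, n_signers=1, n_items=1, seed=8))
        traj = trials[0].trajectory
        n = traj.n_samples
        for start in (n // 3, n // 3 + 20):  # two non-adjacent 7-sample runs
            traj.missing[start : start + 7] = True
        assert max(missing_run_lengths(traj.missing)) == 7
        kept, _ = exclude_gap_trials(trials, max_gap_samples=12)
        assert len(kept) == len(trials)

    def test_empty_input(self):
        kept, report = exclude_gap_trials([])
        assert kept == [] and report.n_gap_excluded == 0


class TestDisplacementOutliers:
    def _uniform_trials(self, n_pairs=10, side=100.0):
        trials = []
        for k in range(n_pairs):
            for cond in ("non_communicative", "communicative"):
                trials.append(
                    make_record(square_path_trajectory(side_mm=side),
                                item=f"item{k:02d}", condition=cond)
                )
        return trials

    def test_one_low_displacement_trial_and_counterpart_removed(self):
        trials = self._uniform_trials(10)
        lone = trials[0].trajectory
        lone.x = lone.home_point[0] + 0.01 * (lone.x - lone.home_point[0])
        lone.y = lone.home_point[1] + 0.01 * (lone.y - lone.home_point[1])
        # direct arithmetic oracle over the 20 per-participant displacements
        disp = np.array([tr.trajectory.max_displacement_mm() for tr in trials])
        thresh = disp.mean() - 3 * disp.std(ddof=1)
        assert disp[0] < thresh and np.all(disp[1:] >= thresh)
        kept, report = exclude_displacement_outliers(trials, k_sd=3)
        assert len(kept) == 18
        assert report.n_displacement_excluded == 1
        assert report.n_pair_propagated == 1
        by_cond = {}
        for tr in kept:
            by_cond[tr.condition] = by_cond.get(tr.condition, 0) + 1
        assert by_cond["communicative"] == by_cond["non_communicative"] == 9

    def test_equal_displacements_remove_nothing(self):
        trials = self._uniform_trials(5)
        kept, report = exclude_displacement_outliers(trials)
        assert len(kept) == 10 and report.n_displacement_excluded == 0

    def test_idempotent(self):
        trials = self._uniform_trials(6)
        lone = trials[2].trajectory
        lone.x = 0.01 * lone.x
        lone.y = 0.01 * lone.y
        once, _ = exclude_displacement_outliers(trials)
        twice, rep2 = exclude_displacement_outliers(once)
        assert [tr.uid for tr in once] == [tr.uid for tr in twice]
        assert rep2.n_displacement_excluded == 0


def test_full_cascade_balances_conditions_per_group():
    trials = gen_cohort(CohortConfig(n_speakers=3, n_signers=2, n_items=3, seed=6))
    # corrupt one trial with a long gap (after resampling its counterpart
    # survives only if the balance guarantee removes it)
    trials = inject_artifacts(trials, gap_run_lengths=[400])
    kept, report = preprocess_trials(trials)
    counts = {}
    for tr in kept:
        counts.setdefault(tr.group, {}).setdefault(tr.condition, 0)
        counts[tr.group][tr.condition] += 1
    for grp, by_cond in counts.items():
        assert by_cond["communicative"] == by_cond["non_communicative"]
    total_out = sum(report.n_retained.values())
    total_in = sum(report.n_input.values())
    assert total_out < total_in


def test_tidy_csv_round_trip(tmp_path):
    trials = gen_cohort(CohortConfig(n_speakers=2, n_signers=1, n_items=2, seed=13))
    trials = inject_artifacts(trials, gap_run_lengths=[5])
    path = tmp_path / "trials.csv"
    write_trials(trials, path)
    back = read_trials(path)
    assert [tr.uid for tr in back] == [tr.uid for tr in trials]
    for a, b in zip(trials, back):
        np.testing.assert_allclose(
            a.trajectory.x[~a.trajectory.missing],
            b.trajectory.x[~b.trajectory.missing],
            atol=1e-9,
        )
        np.testing.assert_array_equal(a.trajectory.missing, b.trajectory.missing)
        assert a.trajectory.home_point == pytest.approx(b.trajectory.home_point)


def test_non_monotone_time_rejected(tmp_path):
    trials = gen_cohort(CohortConfig(n_speakers=1, n_signers=1, n_items=1, seed=3))
    path = tmp_path / "bad.csv"
    write_trials(trials, path)
    txt = path.read_text().splitlines()
    txt[2], txt[3] = txt[3], txt[2]  # swap two sample rows
    path.write_text("\n".join(txt) + "\n")
    with pytest.raises(DataError, match="monotone"):
        read_trials(path)


def test_missing_columns_reported(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("participant_id,group\nA,speaker\n")
    with pytest.raises(DataError, match="missing required columns"):
        read_trials(path)
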