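"""Feature oracles: jerk closed form, brute-force SampEn, rhythm arithmetic."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinesig.features import (
    EntropyParams,
    FeatureNA,
    compute_features,
    descriptive_features,
    jerkiness,
    max_covered_area,
    rhythmicity,
    sample_entropy,
    segment_strokes_holds,
)
from kinesig.speed import SpeedProfile, compute_speed_2d
from kinesig.synthetic import CohortConfig, StrokeChainConfig, gen_cohort, gen_trajectory
from kinesig.trajectory import Trajectory

from conftest import make_record, min_jerk_trajectory, square_path_trajectory


def brute_force_sampen(x, m=2, tau=1, r_factor=0.2):
    """Independent O(n²) template-counting oracle (explicit loops)."""
    x = np.asarray(x, float)
    r = r_factor * np.std(x, ddof=1)
    n_t = x.size - m * tau
    a = b = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            dm = max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(m))
            if dm <= r:
                b += 1
                dm1 = max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(m + 1))
                if dm1 <= r:
                    a += 1
    return -math.log(a / b)


class TestJerkiness:
    def test_unit_minimum_jerk_stroke_closed_form(self):
        # analytic value: integral of squared third derivative = 720,
        # peak speed = 1.875, duration 1 -> 720 / 1.875² = 204.8
        traj = min_jerk_trajectory(1.0, 1.0, hz=120.0)
        pre, log_pre = jerkiness(compute_speed_2d(traj, smooth=False))
        assert pre == pytest.approx(204.8, rel=0.02)
        assert log_pre == pytest.approx(math.log(pre))

    def test_dimensionless_under_amplitude_and_duration_scaling(self):
        # same shape, same number of samples: amplitude x5, duration x2
        a = compute_speed_2d(min_jerk_trajectory(1.0, 1.0, hz=120.0), smooth=False)
        b = compute_speed_2d(min_jerk_trajectory(5.0, 2.0, hz=60.0), smooth=False)
        ja, jb = jerkiness(a)[0], jerkiness(b)[0]
        assert jb == pytest.approx(ja, rel=1e-6)

    def test_constant_speed_interior_contributes_nothing(self):
        t = np.arange(600) / 120.0
        v = np.full(t.size, 80.0)
        prof = SpeedProfile(t=t, v=v, jerk=np.zeros_like(v), duration_s=t[-1], sampling_hz=120.0)
        assert jerkiness(prof)[0] == 0.0

    def test_zero_speed_is_na(self):
        t = np.arange(100) / 120.0
        prof = SpeedProfile(t=t, v=np.zeros_like(t), jerk=np.zeros_like(t),
                            duration_s=t[-1], sampling_hz=120.0)
        with pytest.raises(FeatureNA):
            jerkiness(prof)

    def test_noise_increases_expected_jerkiness(self):
        quiet, noisy = [], []
        for seed in range(200):
            cfg_q = StrokeChainConfig(noise_sd_mm=0.2, sampling_hz=120.0, seed=seed)
            cfg_n = StrokeChainConfig(noise_sd_mm=0.8, sampling_hz=120.0, seed=seed)
            quiet.append(jerkiness(compute_speed_2d(gen_trajectory(cfg_q)))[1])
            noisy.append(jerkiness(compute_speed_2d(gen_trajectory(cfg_n)))[1])
        assert np.mean(noisy) > np.mean(quiet)


class TestSampleEntropy:
    def test_matches_brute_force_oracle(self, rng):
        for n in (60, 150, 300):
            x = rng.normal(size=n).cumsum()
            assert sample_entropy(x) == pytest.approx(brute_force_sampen(x), abs=1e-12)

    def test_matches_brute_force_with_delay_and_m(self, rng):
        x = rng.normal(size=120)
        params = EntropyParams(m=3, tau=2, r_factor=0.3)
        assert sample_entropy(x, params) == pytest.approx(
            brute_force_sampen(x, m=3, tau=2, r_factor=0.3), abs=1e-12
        )

    def test_constant_series_zero_entropy(self):
        x = np.full(100, 2.5)
        x[0] += 0.0
        # constant: every template matches every other; A/B = 1
        assert sample_entropy(x, EntropyParams(r_factor=0.2)) == pytest.approx(0.0)

    def test_matches_independent_r_implementation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=150).cumsum()
        ours = sample_entropy(x)
        sd = np.std(x, ddof=1)
        script = (
            f"x <- c({','.join(f'{v:.17g}' for v in x)});"
            f"cat(pracma::sample_entropy(x, edim=2, r={0.2 * sd:.17g}, tau=1))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), rel=1e-6)

    def test_periodic_series_less_entropic_than_permutations(self, rng):
        x = np.tile([1.0, -1.0], 100) + 0.01 * rng.normal(size=200)
        base = sample_entropy(x)
        wins = 0
        for _ in range(100):
            perm = rng.permutation(x)
            try:
                wins += base < sample_entropy(perm)
            except FeatureNA:
                wins += 1  # no matches at all: maximally irregular
        assert wins >= 95

    def test_entropy_non_increasing_in_tolerance(self, rng):
        x = rng.normal(size=200).cumsum()
        vals = [sample_entropy(x, EntropyParams(r_factor=rf)) for rf in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_short_series_na(self):
        with pytest.raises(FeatureNA):
            sample_entropy(np.zeros(10))


class TestSegmentation:
    def test_single_bell_one_stroke_two_holds(self):
        traj = min_jerk_trajectory(100.0, 1.0, hz=120.0)
        seg = segment_strokes_holds(compute_speed_2d(traj, smooth=False), hold_threshold=15.0)
        assert seg.n_strokes == 1
        assert seg.n_holds == 2  # lead-in and tail below threshold

    def test_all_below_threshold_single_hold_no_strokes(self):
        t = np.arange(120) / 120.0
        prof = SpeedProfile(t=t, v=np.full(t.size, 1.0), jerk=np.zeros(t.size),
                            duration_s=t[-1], sampling_hz=120.0)
        seg = segment_strokes_holds(prof, hold_threshold=15.0)
        assert seg.n_strokes == 0
        assert seg.hold_spans == [(0, 120)]

    def test_three_bell_intervals_match_construction(self):
        cfg = StrokeChainConfig(n_strokes=3, interstroke_interval_sd_s=0.0,
                                noise_sd_mm=0.0, sampling_hz=120.0, seed=2)
        seg = segment_strokes_holds(compute_speed_2d(gen_trajectory(cfg), smooth=False))
        assert seg.n_strokes == 3
        np.testing.assert_allclose(
            seg.stroke_intervals_s, cfg.interstroke_interval_mean_s, atol=1.5 / 120.0
        )


class TestRhythmicity:
    def test_two_interval_arithmetic_oracle(self):
        val, clamped = rhythmicity(np.array([0.3, 0.5]))
        sd = np.std([0.3, 0.5], ddof=1)  # = 0.1414...
        assert val == pytest.approx(-math.log(sd), abs=1e-12)
        assert val == pytest.approx(1.956, abs=1e-3)
        assert not clamped

    def test_equal_intervals_clamped_and_flagged(self):
        val, clamped = rhythmicity(np.array([0.4, 0.4, 0.4]))
        assert clamped
        assert val == pytest.approx(-math.log(1.0 / 120.0))

    def test_single_interval_na(self):
        with pytest.raises(FeatureNA):
            rhythmicity(np.array([0.5]))

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_log_sd_shift_law(self, c):
        iv = np.array([0.2, 0.35, 0.3, 0.55])
        base, _ = rhythmicity(iv)
        scaled, _ = rhythmicity(c * iv)
        assert scaled == pytest.approx(base - math.log(c), abs=1e-9)

    def test_interval_sd_increase_lowers_expected_rhythmicity(self):
        tight, loose = [], []
        for seed in range(200):
            for sd_s, acc in ((0.02, tight), (0.12, loose)):
                cfg = StrokeChainConfig(n_strokes=5, interstroke_interval_sd_s=sd_s,
                                        noise_sd_mm=0.0, sampling_hz=120.0, seed=seed)
                seg = segment_strokes_holds(compute_speed_2d(gen_trajectory(cfg), smooth=False))
                try:
                    acc.append(rhythmicity(seg.stroke_intervals_s)[0])
                except FeatureNA:
                    pass
        assert np.mean(loose) < np.mean(tight)


class TestSpatial:
    def test_rectangle_area(self):
        t = np.arange(120) / 120.0
        x = np.linspace(0, 100, t.size)
        y = np.linspace(0, 50, t.size)
        traj = Trajectory(t=t, x=x, y=y, z=np.zeros_like(t),
                          missing=np.zeros(t.size, bool), sampling_hz=120.0)
        assert max_covered_area(traj) == pytest.approx(5000.0)

    def test_pure_axis_motion_zero_area(self):
        traj = min_jerk_trajectory(100.0, 1.0, hz=120.0, axis="x")
        assert max_covered_area(traj) == pytest.approx(0.0)

    def test_translation_invariance_with_home(self):
        traj = square_path_trajectory()
        shifted = traj.copy()
        shifted.x += 30.0
        shifted.y -= 10.0
        shifted.home_point = (30.0, -10.0, 0.0)
        assert max_covered_area(shifted) == pytest.approx(max_covered_area(traj))


class TestDescriptive:
    def test_uniform_motion(self):
        t = np.arange(240) / 120.0
        traj = Trajectory(t=t, x=120.0 * t, y=np.zeros_like(t), z=np.zeros_like(t),
                          missing=np.zeros(t.size, bool), sampling_hz=120.0)
        prof = compute_speed_2d(traj, smooth=False)
        d = descriptive_features(prof, traj)
        assert d["peak_speed_mm_s"] == pytest.approx(120.0, rel=1e-6)
        assert d["mean_accel_mm_s2"] < 1.0

    def test_min_jerk_peak_speed_closed_form(self):
        traj = min_jerk_trajectory(1.0, 1.0, hz=120.0)
        d = descriptive_features(compute_speed_2d(traj, smooth=False), traj)
        assert d["peak_speed_mm_s"] == pytest.approx(1.875, rel=1e-3)

    def test_table_planar_trajectory_has_zero_height(self):
        traj = gen_trajectory(StrokeChainConfig(sampling_hz=120.0, seed=1))
        d = descriptive_features(compute_speed_2d(traj), traj)
        assert d["height_mm"] == pytest.approx(0.0, abs=1e-9)


def test_feature_table_covers_cohort_with_reasons():
    trials = gen_cohort(CohortConfig(n_speakers=2, n_signers=1, n_items=2, seed=5,
                                      ))
    table = compute_features(trials)
    assert len(table) == len(trials)
    assert set(table["condition"]) == {"non_communicative", "communicative"}
    assert table["log_jerkiness"].notna().all()
    assert table["max_area_mm2"].ge(0).all()
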