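"""Duty-cycle schedule and synthetic stream generation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wearcopd.config import SECONDS_PER_DAY, STANDARD_GRAVITY, CohortConfig, ConfigError
from wearcopd import synthetic
from wearcopd.synthetic import (
    generate_schedule,
    simulate_accelerometer,
    simulate_diary,
    simulate_heart_rate,
    simulate_latent_state,
    study_windows,
)


def covered_minutes(windows, day_start, day_end):
    """Brute-force enumeration: which whole minutes are recorded."""
    out = []
    for m in range(int(day_start) // 60, int(day_end) // 60):
        mid = m * 60 + 30
        out.append(any(on <= mid < off for on, off in windows))
    return out


class TestSchedule:
    def test_default_day_has_144_two_minute_windows(self, default_config):
        w = generate_schedule(0, SECONDS_PER_DAY, default_config)
        assert len(w) == 144
        assert all(off - on == 120 for on, off in w)

    def test_always_on_merges_to_single_window(self):
        cfg = CohortConfig(duty_on_minutes=10, duty_cycle_minutes=10)
        assert generate_schedule(0, SECONDS_PER_DAY, cfg) == [(0.0, 86400.0)]

    def test_ten_minute_day_has_one_window(self, default_config):
        assert generate_schedule(0, 600, default_config) == [(0.0, 120.0)]

    def test_non_positive_duration_rejected(self, default_config):
        with pytest.raises(ConfigError):
            generate_schedule(100, 100, default_config)

    @given(
        on=st.integers(1, 10),
        cycle_extra=st.integers(0, 20),
        n_cycles=st.integers(1, 30),
    )
    def test_coverage_fraction_matches_duty_cycle(self, on, cycle_extra, n_cycles):
        # over complete cycles, recorded minutes / total = on / cycle exactly
        cycle = on + cycle_extra
        cfg = CohortConfig(duty_on_minutes=on, duty_cycle_minutes=cycle)
        day_end = n_cycles * cycle * 60
        w = generate_schedule(0, day_end, cfg)
        minutes = covered_minutes(w, 0, day_end)
        assert sum(minutes) * cycle == on * len(minutes)
        # and each complete cycle contains exactly `on` recorded minutes
        for c in range(n_cycles):
            assert sum(minutes[c * cycle : (c + 1) * cycle]) == on

    def test_windows_are_disjoint_and_ordered(self, default_config):
        w = generate_schedule(0, SECONDS_PER_DAY, default_config)
        assert all(a[1] <= b[0] for a, b in zip(w, w[1:]))


class TestLatentState:
    def test_zero_rate_means_no_episodes(self):
        cfg = CohortConfig(episode_rate_per_day=0.0)
        st_ = simulate_latent_state(cfg, 0)
        assert not st_.exacerbation.any()

    def test_determinism(self, default_config):
        a = simulate_latent_state(default_config, 3)
        b = simulate_latent_state(default_config, 3)
        assert np.array_equal(a.exacerbation, b.exacerbation)
        assert np.array_equal(a.activity_profile, b.activity_profile)
        assert a.baseline_hr == b.baseline_hr

    def test_saturated_rate_flags_every_day(self):
        # rate 1 with a mean phase far beyond the study flags all days
        cfg = CohortConfig(
            study_days=30, episode_rate_per_day=1.0,
            mean_episode_symptom_days=10_000.0,
        )
        for seed in range(100):
            assert simulate_latent_state(cfg, seed).exacerbation.all()

    def test_minimum_episode_length_is_two_days(self):
        cfg = CohortConfig(study_days=365, episode_rate_per_day=0.05,
                           mean_episode_symptom_days=1.0)
        flags = simulate_latent_state(cfg, 1).exacerbation
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(
            ([0], flags.view(np.int8), [0])))).reshape(-1, 2), axis=1)
        assert runs.size > 0 and (runs >= 2).all()

    def test_elevated_days_expect_score_above_threshold(self, default_config):
        st_ = simulate_latent_state(default_config.replace(episode_rate_per_day=1.0), 0)
        p = st_.symptom_probs[st_.exacerbation][0]
        assert 5 * p[:3].sum() + p[3:].sum() > 5


class TestAccelerometer:
    def test_two_minute_window_has_2400_samples(self, default_config):
        st_ = simulate_latent_state(default_config, 0)
        df = simulate_accelerometer(st_, [(0.0, 120.0)], default_config)
        assert len(df) == 2400
        ts = df["timestamp"].to_numpy("datetime64[ms]").astype("int64") / 1000
        assert np.allclose(np.diff(ts), 1 / default_config.accel_hz)

    def test_sedentary_zero_noise_is_pure_gravity(self):
        cfg = CohortConfig(accel_noise_sd=0.0, activity_mix=(1.0, 0.0, 0.0))
        st_ = simulate_latent_state(cfg, 0)
        w = study_windows(cfg, st_, range(1))
        df = simulate_accelerometer(st_, w, cfg)
        mag = np.linalg.norm(df[["ax", "ay", "az"]].to_numpy(), axis=1)
        assert np.allclose(mag, STANDARD_GRAVITY)

    def test_no_sample_outside_recording_windows(self, small_config):
        st_ = simulate_latent_state(small_config, 0)
        w = study_windows(small_config, st_)
        df = simulate_accelerometer(st_, w, small_config)
        ts = df["timestamp"].to_numpy("datetime64[ms]").astype("int64") / 1000
        inside = np.zeros(len(ts), dtype=bool)
        for on, off in w:
            inside |= (ts >= on) & (ts < off)
        assert inside.all()

    def test_charging_flag_matches_charging_interval(self, small_config):
        st_ = simulate_latent_state(small_config, 0)
        w = study_windows(small_config, st_, range(2))
        df = simulate_accelerometer(st_, w, small_config)
        ts = df["timestamp"].to_numpy("datetime64[ms]").astype("int64") / 1000
        sec = (ts - synthetic.study_epoch(small_config)) % SECONDS_PER_DAY
        lo, hi = st_.charging_interval
        assert np.array_equal(df["charging"].to_numpy(), (sec >= lo) & (sec < hi))

    def test_unreliable_fraction_is_respected(self):
        cfg = CohortConfig(unreliable_fraction=0.2)
        st_ = simulate_latent_state(cfg, 0)
        df = simulate_accelerometer(st_, study_windows(cfg, st_, range(1)), cfg)
        frac = 1 - df["reliable"].mean()
        assert frac == pytest.approx(0.2, abs=0.02)


class TestHeartRate:
    def test_zero_noise_sedentary_equals_baseline(self):
        cfg = CohortConfig(hr_noise_sd=0.0, activity_mix=(1.0, 0.0, 0.0))
        st_ = simulate_latent_state(cfg, 0)
        df = simulate_heart_rate(st_, study_windows(cfg, st_, range(1)), cfg)
        assert np.allclose(df["bpm"], st_.baseline_hr)

    def test_same_seed_gives_identical_stream(self, small_config):
        st_ = simulate_latent_state(small_config, 1)
        w = study_windows(small_config, st_)
        pd.testing.assert_frame_equal(
            simulate_heart_rate(st_, w, small_config),
            simulate_heart_rate(st_, w, small_config),
        )

    def test_sampling_interval(self, default_config):
        st_ = simulate_latent_state(default_config, 0)
        df = simulate_heart_rate(st_, [(0.0, 120.0)], default_config)
        assert len(df) == 60  # 120 s at one sample per 2 s
        assert (df["bpm"] >= default_config.hr_floor).all()

    def test_valid_mean_tracks_baseline_over_study(self):
        # activity offsets silenced via an all-sedentary profile
        cfg = CohortConfig(activity_mix=(1.0, 0.0, 0.0), study_days=90)
        errs = []
        for seed in range(5):
            st_ = simulate_latent_state(cfg.replace(seed=seed), 0)
            df = simulate_heart_rate(st_, study_windows(cfg, st_), cfg.replace(seed=seed))
            valid = df[~df["charging"] & df["reliable"]]
            errs.append(abs(valid["bpm"].mean() - st_.baseline_hr))
        assert max(errs) < 2.0


class TestDiarySimulation:
    def test_full_compliance_yields_every_day(self, default_config):
        cfg = default_config.replace(survey_compliance=1.0)
        st_ = simulate_latent_state(cfg, 0)
        assert len(simulate_diary(st_, cfg)) == cfg.study_days

    def test_zero_compliance_yields_empty_diary(self, default_config):
        cfg = default_config.replace(survey_compliance=0.0)
        st_ = simulate_latent_state(cfg, 0)
        assert simulate_diary(st_, cfg) == []

    def test_completion_fraction_tracks_compliance(self):
        # law of large numbers over 1000 simulated days
        cfg = CohortConfig(study_days=1000, survey_compliance=0.717)
        st_ = simulate_latent_state(cfg, 0)
        frac = len(simulate_diary(st_, cfg)) / cfg.study_days
        assert frac == pytest.approx(0.717, abs=0.03)

    def test_dates_are_unique_and_in_range(self, default_config):
        st_ = simulate_latent_state(default_config, 2)
        entries = simulate_diary(st_, default_config)
        dates = [e.date for e in entries]
        assert len(set(dates)) == len(dates)
        start = dt.date.fromisoformat(default_config.start_date)
        assert all(
            start <= d < start + dt.timedelta(days=default_config.study_days)
            for d in dates
        )
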