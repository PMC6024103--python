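"""Gravity removal, motion counts and activity classification."""

import numpy as np
import pandas as pd
import pytest

from wearcopd.config import ActivityThresholds, CohortConfig, ConfigError
from wearcopd import accelerometry as acc
from wearcopd import synthetic


def make_stream(ts, axes, charging=False, reliable=True):
    axes = np.asarray(axes, float)
    n = len(ts)
    return pd.DataFrame(
        {
            "timestamp": (np.asarray(ts) * 1000).astype("int64").astype("datetime64[ms]"),
            "ax": axes[:, 0],
            "ay": axes[:, 1],
            "az": axes[:, 2],
            "charging": np.broadcast_to(charging, n).copy(),
            "reliable": np.broadcast_to(reliable, n).copy(),
        }
    )


class TestFilter:
    def test_all_charging_filtered_out(self):
        df = make_stream(np.arange(10) * 0.05, np.zeros((10, 3)), charging=True)
        assert len(acc.filter_valid_samples(df)) == 0

    def test_all_valid_unchanged(self):
        df = make_stream(np.arange(10) * 0.05, np.zeros((10, 3)))
        pd.testing.assert_frame_equal(acc.filter_valid_samples(df), df)

    def test_mixed_preserves_order(self):
        df = make_stream(np.arange(10) * 0.05, np.zeros((10, 3)))
        df.loc[[1, 4], "charging"] = True
        df.loc[7, "reliable"] = False
        out = acc.filter_valid_samples(df)
        assert len(out) == 7
        assert out["timestamp"].is_monotonic_increasing


class TestRemoveGravity:
    def test_static_window_leaves_no_motion(self):
        g = np.tile([3.0, -4.0, 7.8], (200, 1))
        motion = acc.remove_gravity(g, sample_hz=20)
        assert np.abs(motion).max() < 1e-9

    def test_sinusoid_amplitude_recovered(self):
        # 2 Hz sinusoid: a 2 s moving average transmits none of it
        # (sinc(fT) = sinc(4) = 0), so the residual is the full sinusoid
        fs, amp = 20.0, 0.7
        t = np.arange(0, 30, 1 / fs)
        sig = np.zeros((t.size, 3))
        sig[:, 0] = 9.81 + amp * np.sin(2 * np.pi * 2.0 * t)
        motion = acc.remove_gravity(sig, fs)
        core = motion[40:-40, 0]  # skip boundary transients
        # RMS comparison avoids the sample-phase dependence of the peak
        assert np.sqrt(np.mean(core**2)) == pytest.approx(amp / np.sqrt(2), rel=0.05)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(300, 3))
        b = rng.normal(size=(300, 3))
        lhs = acc.remove_gravity(a + b, 20)
        rhs = acc.remove_gravity(a, 20) + acc.remove_gravity(b, 20)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            acc.remove_gravity(np.zeros((1, 3)), 20)


class TestMotionCounts:
    def test_zero_motion_gives_zero_counts(self):
        t = np.arange(0, 60, 0.05)
        assert acc.motion_counts(t, np.zeros(t.size)) == 0.0

    def test_constant_magnitude_over_full_minute(self):
        # trapezoid is exact on constants: counts = 60 * m * s_unit
        t = np.arange(0, 60, 0.05)
        m = 1.7
        counts = acc.motion_counts(t, np.full(t.size, m), count_scale=2.0)
        assert counts == pytest.approx(60 * m * 2.0)

    def test_partial_minute_is_rate_rescaled(self):
        t = np.arange(0, 12, 0.05)  # only 12 s covered
        counts = acc.motion_counts(t, np.full(t.size, 1.0))
        assert counts == pytest.approx(60.0)

    def test_sample_rate_halving_changes_counts_below_one_percent(self):
        t = np.arange(0, 60, 0.05)
        m = 2 + np.sin(2 * np.pi * 0.5 * t)  # smooth signal
        full = acc.motion_counts(t, m)
        half = acc.motion_counts(t[::2], m[::2])
        assert abs(half - full) / full < 0.01

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            acc.motion_counts(np.array([0.0]), np.array([1.0]))


class TestClassify:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (0.0, acc.SEDENTARY),
            (50.91, acc.SEDENTARY),
            (50.92, acc.LIGHT),     # boundary: strict inequality
            (100.0, acc.LIGHT),
            (305.36, acc.LIGHT),    # boundary: strict inequality
            (400.0, acc.MVPA),
        ],
    )
    def test_cut_points(self, counts, expected):
        assert acc.classify_minute(counts, ActivityThresholds()) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            acc.classify_minute(-1.0, ActivityThresholds())

    def test_monotone_in_counts(self):
        order = {acc.SEDENTARY: 0, acc.LIGHT: 1, acc.MVPA: 2}
        th = ActivityThresholds()
        grid = np.linspace(0, 500, 200)
        classes = [order[acc.classify_minute(c, th)] for c in grid]
        assert classes == sorted(classes)

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ConfigError):
            ActivityThresholds(sedentary_max=400.0, mvpa_min=300.0)


class TestDailySummary:
    def minutes(self, classes, valid=None):
        n = len(classes)
        valid = [c != acc.INVALID for c in classes] if valid is None else valid
        return pd.DataFrame(
            {
                "minute_start": (np.arange(n) * 60_000).astype("datetime64[ms]"),
                "counts": np.where(valid, 10.0, np.nan),
                "n_samples": 1200,
                "valid": valid,
                "activity_class": classes,
            }
        )

    def test_all_sedentary(self):
        out = acc.daily_activity_summary(self.minutes([acc.SEDENTARY] * 10))
        row = out.iloc[0]
        assert row["pct_sedentary"] == 100.0 and row["pct_mvpa"] == 0.0

    def test_split_percentages(self):
        classes = [acc.SEDENTARY] * 8 + [acc.LIGHT] * 4 + [acc.MVPA] * 4
        row = acc.daily_activity_summary(self.minutes(classes)).iloc[0]
        assert row["pct_sedentary"] == 50.0
        assert row["pct_light"] == 25.0
        assert row["pct_mvpa"] == 25.0
        assert row["valid_minutes"] == 16

    def test_invalid_minutes_excluded_from_denominator(self):
        classes = [acc.SEDENTARY] * 5 + [acc.INVALID] * 5
        row = acc.daily_activity_summary(self.minutes(classes)).iloc[0]
        assert row["pct_sedentary"] == 100.0 and row["valid_minutes"] == 5

    def test_all_invalid_day_is_no_data(self):
        row = acc.daily_activity_summary(self.minutes([acc.INVALID] * 5)).iloc[0]
        assert row["valid_minutes"] == 0 and np.isnan(row["pct_sedentary"])

    def test_percentages_always_close_to_hundred(self):
        rng = np.random.default_rng(1)
        classes = list(rng.choice([acc.SEDENTARY, acc.LIGHT, acc.MVPA], size=50))
        row = acc.daily_activity_summary(self.minutes(classes)).iloc[0]
        assert row[["pct_sedentary", "pct_light", "pct_mvpa"]].sum() == pytest.approx(100.0)


class TestEndToEnd:
    def test_counts_invariant_under_rotation(self):
        cfg = CohortConfig(seed=5)
        state = synthetic.simulate_latent_state(cfg, 0)
        windows = synthetic.study_windows(cfg, state, range(1))[60:80]
        df = synthetic.simulate_accelerometer(state, windows, cfg)
        df["reliable"] = True
        df["charging"] = False

        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        rotated = df.copy()
        rotated[["ax", "ay", "az"]] = df[["ax", "ay", "az"]].to_numpy() @ rot.T

        m1 = acc.minute_activity(df, cfg.accel_hz, cfg.thresholds)
        m2 = acc.minute_activity(rotated, cfg.accel_hz, cfg.thresholds)
        c1 = m1[m1["valid"]]["counts"].to_numpy()
        c2 = m2[m2["valid"]]["counts"].to_numpy()
        assert np.abs(c1 - c2).max() / c1.max() < 0.01

    def test_intended_class_recovered_on_synthetic_day(self):
        cfg = CohortConfig(seed=7)
        state = synthetic.simulate_latent_state(cfg, 0)
        windows = synthetic.study_windows(cfg, state, range(1))
        df = synthetic.simulate_accelerometer(state, windows, cfg)
        minutes = acc.minute_activity(
            df, cfg.accel_hz, cfg.thresholds, cfg.count_scale,
            cfg.gravity_window_seconds, cfg.utc_offset_hours,
        )
        valid = minutes[minutes["valid"]]
        ts = valid["minute_start"].to_numpy("datetime64[s]").astype("int64")
        local = ts - synthetic.study_epoch(cfg)
        intended = state.activity_profile[local // 86400, (local % 86400) // 3600]
        names = np.array(synthetic.CLASS_NAMES)[intended]
        agreement = (valid["activity_class"].to_numpy() == names).mean()
        assert agreement >= 0.9

    def test_mostly_charging_minutes_marked_invalid(self):
        t = np.arange(0, 120, 0.05)
        df = make_stream(t, np.tile([0, 0, 9.81], (t.size, 1)))
        df.loc[: int(0.6 * len(df)), "charging"] = True
        minutes = acc.minute_activity(df, 20.0)
        assert (minutes["activity_class"] == acc.INVALID).iloc[0]
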