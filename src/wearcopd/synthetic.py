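"""Synthetic smartwatch cohorts: duty-cycled sensor streams and diaries.

Generates per-patient datasets with the statistical structure the
downstream analysis assumes, so every stage is testable without access to
device recordings:

* a recording schedule that switches the sensors on for 2 of every 10
  minutes (battery-preserving duty cycle), aligned to cycle boundaries
  from local midnight;
* a day-level two-state exacerbation process that drives the 8 daily
  symptom probabilities (majors strongly elevated during episodes, so the
  expected daily score clears the onset threshold);
* 20 Hz tri-axial accelerometer bursts — a constant 9.81 m/s^2 gravity
  vector with a fresh random orientation per recording window, plus
  zero-mean white motion whose amplitude follows the hour's intended
  activity class, plus sensor noise;
* a heart-rate stream at a fixed sampling interval — per-patient baseline
  plus an activity-dependent offset plus noise, floored at 30 bpm;
* a daily diary completed with probability ``survey_compliance``.

All randomness flows from ``(config.seed, patient index)`` through
:class:`numpy.random.SeedSequence`, so cohorts are bit-reproducible and
patients can be generated independently.  Timestamps are UTC; a "day" is
a half-open 24 h window from local midnight (configurable fixed UTC
offset).  Samples are flagged ``charging`` inside the daily charging
interval and ``reliable`` except for a random ``unreliable_fraction``;
hours when the watch is neither worn nor charging produce no samples.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accelerometry import ACCEL_COLUMNS
from .config import (
    SECONDS_PER_DAY,
    STANDARD_GRAVITY,
    CohortConfig,
    ConfigError,
)
from .diary import SYMPTOMS, SymptomDiaryEntry
from .vitals import HR_COLUMNS

# activity class codes used in the latent per-hour profile
CLASS_SEDENTARY, CLASS_LIGHT, CLASS_MVPA = 0, 1, 2
CLASS_NAMES = ("sedentary", "light", "mvpa")


@dataclass(frozen=True)
class LatentPatientState:
    """Ground truth for one simulated patient (recovery-test oracle)."""

    patient_index: int
    exacerbation: np.ndarray          # (study_days,) bool
    symptom_probs: np.ndarray         # (study_days, 8) in [0, 1]
    activity_profile: np.ndarray      # (study_days, 24) class codes
    wear_intervals: list[tuple[float, float]]  # seconds of local day
    charging_interval: tuple[float, float]     # seconds of local day
    baseline_hr: float

    def episode_onsets(self) -> list[int]:
        """Day indices where an injected episode begins."""
        flags = self.exacerbation
        prev = np.concatenate(([False], flags[:-1]))
        return list(np.flatnonzero(flags & ~prev))


def _patient_rng(config: CohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    # one independent generator per (patient, purpose) so adding samples to
    # one stream never perturbs another
    ss = np.random.SeedSequence((config.seed, patient_index, stream))
    return np.random.default_rng(ss)


def study_epoch(config: CohortConfig) -> int:
    """UTC epoch seconds of local midnight on day 0."""
    d = dt.date.fromisoformat(config.start_date)
    midnight_utc = dt.datetime(d.year, d.month, d.day, tzinfo=dt.timezone.utc)
    return int(midnight_utc.timestamp()) - int(round(config.utc_offset_hours * 3600))


def generate_schedule(
    day_start: float, day_end: float, config: CohortConfig
) -> list[tuple[float, float]]:
    """Recording windows for one day under the duty cycle.

    Returns non-overlapping half-open ``[on, off)`` windows in seconds.
    Cycles of ``duty_cycle_minutes`` start at ``day_start``; the first
    ``duty_on_minutes`` of each cycle are recorded.  Adjacent windows are
    merged (relevant in the always-on limit); windows are clipped to
    ``day_end``.
    """
    if day_end <= day_start:
        raise ConfigError("day_end must be after day_start")
    cycle = config.duty_cycle_minutes * 60.0
    on = config.duty_on_minutes * 60.0
    windows: list[tuple[float, float]] = []
    t = float(day_start)
    while t < day_end:
        w = (t, min(t + on, float(day_end)))
        if windows and windows[-1][1] == w[0]:
            windows[-1] = (windows[-1][0], w[1])
        else:
            windows.append(w)
        t += cycle
    return windows


def study_windows(config: CohortConfig, state: LatentPatientState | None = None,
                  days: range | None = None) -> list[tuple[float, float]]:
    """Concatenated recording windows over the study (or a subset of days),
    clipped to the hours the watch is on the wrist or on the charger."""
    epoch0 = study_epoch(config)
    if days is None:
        days = range(config.study_days)
    out: list[tuple[float, float]] = []
    for d in days:
        start = epoch0 + d * SECONDS_PER_DAY
        for on, off in generate_schedule(start, start + SECONDS_PER_DAY, config):
            if state is None:
                out.append((on, off))
                continue
            presence = [state.charging_interval] + state.wear_intervals
            for lo, hi in presence:
                a = max(on, start + lo)
                b = min(off, start + hi)
                if b > a:
                    out.append((a, b))
    out.sort()
    return out


def simulate_latent_state(config: CohortConfig, patient_seed: int) -> LatentPatientState:
    """Draw one patient's ground truth, deterministically in (config, seed).

    Episodes follow a two-state day process: a non-episode day enters an
    episode with probability ``episode_rate_per_day``; the
    elevated-symptom phase lasts a geometric number of days with mean
    ``mean_episode_symptom_days``, never fewer than 2 (the onset rule
    needs two consecutive high days to be recoverable at all).  A
    refractory gap of ``min_inter_episode_days`` follows each phase before
    a new episode may begin, so distinct injected episodes stay separable
    by the 5-zero-day resolution rule.
    """
    rng = _patient_rng(config, patient_seed, 0)
    n = config.study_days

    exac = np.zeros(n, dtype=bool)
    d = 0
    while d < n:
        # an episode never starts on the final day: truncation at the study
        # boundary would violate the 2-day minimum duration
        if d < n - 1 and rng.random() < config.episode_rate_per_day:
            length = max(2, int(rng.geometric(1.0 / config.mean_episode_symptom_days)))
            exac[d : d + length] = True
            d += length + config.min_inter_episode_days
        else:
            d += 1

    probs = np.empty((n, 8))
    probs[:, :3] = np.where(exac[:, None], config.episode_major_p, config.baseline_major_p)
    probs[:, 3:] = np.where(exac[:, None], config.episode_minor_p, config.baseline_minor_p)

    # hours: charging first (overnight), then wear; remaining hours off-wrist
    ch = config.charging_hours_per_day
    wear_end = ch + config.wear_hours_per_day
    charging_interval = (0.0, ch * 3600.0)
    wear_intervals = [(ch * 3600.0, wear_end * 3600.0)]

    hours = np.arange(24)
    awake = (hours >= ch) & (hours < wear_end)
    profile = np.full((n, 24), CLASS_SEDENTARY, dtype=np.int8)
    draws = rng.choice(3, size=(n, 24), p=list(config.activity_mix))
    profile[:, awake] = draws[:, awake]

    baseline = float(rng.normal(config.hr_baseline_mean, config.hr_baseline_sd))
    return LatentPatientState(
        patient_index=patient_seed,
        exacerbation=exac,
        symptom_probs=probs,
        activity_profile=profile,
        wear_intervals=wear_intervals,
        charging_interval=charging_interval,
        baseline_hr=max(40.0, baseline),
    )


def _window_timestamps(windows, interval: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample times for each half-open window at fixed spacing.

    Returns (timestamps, window_index).  Uses a broadcast fast path when
    all windows share one duration.
    """
    if not windows:
        return np.empty(0), np.empty(0, dtype=np.int64)
    starts = np.array([w[0] for w in windows])
    counts = np.array(
        [max(0, int(np.ceil((off - on) / interval - 1e-9))) for on, off in windows]
    )
    if len(set(counts)) == 1:
        k = int(counts[0])
        ts = (starts[:, None] + np.arange(k) * interval).ravel()
        idx = np.repeat(np.arange(len(windows)), k)
        return ts, idx
    ts = np.concatenate(
        [on + np.arange(c) * interval for (on, _), c in zip(windows, counts)]
    )
    idx = np.repeat(np.arange(len(windows)), counts)
    return ts, idx


def _sample_flags(
    ts: np.ndarray,
    epoch0: int,
    state: LatentPatientState,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(charging, reliable, day index, hour-class code) per sample time."""
    local = ts - epoch0
    day = (local // SECONDS_PER_DAY).astype(np.int64)
    sec_of_day = local - day * SECONDS_PER_DAY
    lo, hi = state.charging_interval
    charging = (sec_of_day >= lo) & (sec_of_day < hi)
    reliable = rng.random(ts.size) >= config.unreliable_fraction
    hour = (sec_of_day // 3600).astype(np.int64)
    day_c = np.clip(day, 0, state.activity_profile.shape[0] - 1)
    cls = state.activity_profile[day_c, hour]
    return charging, reliable, day, cls


def simulate_accelerometer(
    state: LatentPatientState,
    windows: list[tuple[float, float]],
    config: CohortConfig,
) -> pd.DataFrame:
    """20 Hz tri-axial stream over the given recording windows."""
    rng = _patient_rng(config, state.patient_index, 1)
    epoch0 = study_epoch(config)
    ts, widx = _window_timestamps(windows, 1.0 / config.accel_hz)
    n = ts.size
    if n == 0:
        return pd.DataFrame(columns=ACCEL_COLUMNS)

    # per-window gravity orientation: uniform on the sphere
    nw = len(windows)
    v = rng.normal(size=(nw, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    gravity = STANDARD_GRAVITY * v[widx]

    charging, reliable, _, cls = _sample_flags(ts, epoch0, state, config, rng)
    amp = np.array(
        [config.motion_amp_sedentary, config.motion_amp_light, config.motion_amp_mvpa]
    )[cls]
    motion = rng.normal(size=(n, 3)) * amp[:, None]
    noise = rng.normal(scale=config.accel_noise_sd, size=(n, 3)) \
        if config.accel_noise_sd > 0 else 0.0
    acc = gravity + motion + noise

    return pd.DataFrame(
        {
            "timestamp": (np.round(ts * 1000).astype("int64")).astype("datetime64[ms]"),
            "ax": acc[:, 0],
            "ay": acc[:, 1],
            "az": acc[:, 2],
            "charging": charging,
            "reliable": reliable,
        }
    )


def simulate_heart_rate(
    state: LatentPatientState,
    windows: list[tuple[float, float]],
    config: CohortConfig,
) -> pd.DataFrame:
    """Heart-rate stream at ``hr_interval_seconds`` over the windows."""
    rng = _patient_rng(config, state.patient_index, 2)
    epoch0 = study_epoch(config)
    ts, _ = _window_timestamps(windows, config.hr_interval_seconds)
    if ts.size == 0:
        return pd.DataFrame(columns=HR_COLUMNS)
    charging, reliable, _, cls = _sample_flags(ts, epoch0, state, config, rng)
    offset = np.array([0.0, config.hr_offset_light, config.hr_offset_mvpa])[cls]
    noise = rng.normal(scale=config.hr_noise_sd, size=ts.size) \
        if config.hr_noise_sd > 0 else 0.0
    bpm = np.maximum(config.hr_floor, state.baseline_hr + offset + noise)
    return pd.DataFrame(
        {
            "timestamp": (np.round(ts * 1000).astype("int64")).astype("datetime64[ms]"),
            "bpm": bpm,
            "charging": charging,
            "reliable": reliable,
        }
    )


def simulate_diary(
    state: LatentPatientState, config: CohortConfig
) -> list[SymptomDiaryEntry]:
    """Daily diary entries; each day is completed with probability
    ``survey_compliance`` and symptoms drawn from that day's probabilities."""
    rng = _patient_rng(config, state.patient_index, 3)
    start = dt.date.fromisoformat(config.start_date)
    entries: list[SymptomDiaryEntry] = []
    pid = f"P{state.patient_index:03d}"
    present = rng.random(config.study_days) < config.survey_compliance
    draws = rng.random((config.study_days, 8)) < state.symptom_probs
    for d in range(config.study_days):
        if not present[d]:
            continue
        fields = {name: bool(draws[d, j]) for j, name in enumerate(SYMPTOMS)}
        entries.append(
            SymptomDiaryEntry(
                patient_id=pid, date=start + dt.timedelta(days=d), **fields
            )
        )
    return entries


def generate_patient(
    config: CohortConfig,
    patient_index: int,
    accel_days: int | None = None,
) -> dict:
    """Generate one patient's full dataset.

    ``accel_days`` optionally limits the accelerometer stream to the first
    k study days (the raw 20 Hz stream is by far the bulkiest artifact;
    diaries and heart rate always cover the whole study).
    """
    state = simulate_latent_state(config, patient_index)
    windows = study_windows(config, state)
    if accel_days is None or accel_days >= config.study_days:
        accel_windows = windows
    else:
        accel_windows = study_windows(config, state, range(accel_days))
    return {
        "state": state,
        "accel": simulate_accelerometer(state, accel_windows, config),
        "hr": simulate_heart_rate(state, windows, config),
        "diary": simulate_diary(state, config),
    }


def truth_dict(state: LatentPatientState, config: CohortConfig) -> dict:
    """JSON-serializable latent-state record written next to the streams."""
    start = dt.date.fromisoformat(config.start_date)
    onsets = state.episode_onsets()
    return {
        "patient_index": state.patient_index,
        "baseline_hr": state.baseline_hr,
        "exacerbation_days": [int(x) for x in np.flatnonzero(state.exacerbation)],
        "episode_onset_dates": [
            (start + dt.timedelta(days=int(d))).isoformat() for d in onsets
        ],
        "activity_profile": state.activity_profile.tolist(),
        "charging_interval_seconds": list(state.charging_interval),
        "wear_intervals_seconds": [list(w) for w in state.wear_intervals],
    }
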