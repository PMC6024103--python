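"""Cohort and pipeline configuration.

A :class:`CohortConfig` fixes every knob of the synthetic study: the
duty-cycled recording schedule (2 minutes recorded out of every 10, the
battery-saving scheme used by the smartwatch platform this package models),
sensor sampling rates, the day-level exacerbation process, symptom
probabilities, wear/charging behaviour and survey compliance.  The defaults
are the study conditions the analysis assumes; see docs/methods.md for the
rationale behind each number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SECONDS_PER_DAY = 86_400
STANDARD_GRAVITY = 9.81  # m/s^2


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ActivityThresholds:
    """Counts-per-minute cut-points separating sedentary / light / MVPA.

    The defaults are the published Android-device cut-points this analysis
    uses: minutes below 50.92 counts/min are sedentary, minutes above
    305.36 counts/min are moderate-to-vigorous physical activity (MVPA),
    and everything in between (boundaries included, the inequalities being
    strict) is light activity.
    """

    sedentary_max: float = 50.92
    mvpa_min: float = 305.36

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_max < self.mvpa_min):
            raise ConfigError(
                f"thresholds must satisfy 0 < sedentary_max < mvpa_min, "
                f"got {self.sedentary_max} and {self.mvpa_min}"
            )


@dataclass(frozen=True)
class CohortConfig:
    # cohort shape
    n_patients: int = 16
    study_days: int = 90
    seed: int = 0
    start_date: str = "2017-01-01"
    utc_offset_hours: float = 0.0

    # recording schedule
    duty_on_minutes: int = 2
    duty_cycle_minutes: int = 10
    accel_hz: float = 20.0
    hr_interval_seconds: float = 2.0

    # day-level exacerbation process: entry hazard per non-episode day and
    # mean length of the elevated-symptom phase (episodes last longer than
    # the symptom phase because resolution needs five consecutive zero days)
    episode_rate_per_day: float = 1.5 / 90
    mean_episode_symptom_days: float = 9.0
    # a fresh episode cannot begin within this many days of the previous
    # symptom phase ending (re-worsening inside this window is clinically a
    # relapse of the same event, and the 5-zero-day resolution rule cannot
    # separate closer events anyway)
    min_inter_episode_days: int = 28

    # wear / charging / reliability
    wear_hours_per_day: float = 16.0
    charging_hours_per_day: float = 8.0
    unreliable_fraction: float = 0.05
    survey_compliance: float = 0.717

    # daily symptom probabilities (3 major, 5 minor items)
    baseline_major_p: float = 0.02
    baseline_minor_p: float = 0.05
    episode_major_p: float = 0.95
    episode_minor_p: float = 0.70

    # accelerometer generative model: white-noise motion amplitude (m/s^2,
    # per axis) by intended class, plus sensor noise
    motion_amp_sedentary: float = 0.0
    motion_amp_light: float = 1.5
    motion_amp_mvpa: float = 6.0
    accel_noise_sd: float = 0.05

    # waking-hour activity-class mix (sedentary, light, MVPA)
    activity_mix: tuple[float, float, float] = (0.64, 0.266, 0.094)

    # heart-rate generative model (bpm)
    hr_baseline_mean: float = 80.6
    hr_baseline_sd: float = 4.5
    hr_noise_sd: float = 3.0
    hr_offset_light: float = 15.0
    hr_offset_mvpa: float = 40.0
    hr_floor: float = 30.0

    # counts pipeline
    count_scale: float = 1.0  # s_unit: counts per (m/s^2 · s)
    gravity_window_seconds: float = 2.0
    thresholds: ActivityThresholds = field(default_factory=ActivityThresholds)

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.study_days <= 0:
            raise ConfigError("n_patients and study_days must be positive")
        if self.duty_on_minutes <= 0 or self.duty_cycle_minutes <= 0:
            raise ConfigError("duty-cycle minutes must be positive")
        if self.duty_on_minutes > self.duty_cycle_minutes:
            raise ConfigError("duty_on_minutes must not exceed duty_cycle_minutes")
        if self.accel_hz <= 0 or self.hr_interval_seconds <= 0:
            raise ConfigError("sampling rates must be positive")
        if not 0 <= self.episode_rate_per_day <= 1:
            raise ConfigError("episode_rate_per_day must be a probability")
        if self.mean_episode_symptom_days <= 0:
            raise ConfigError("mean_episode_symptom_days must be positive")
        if self.min_inter_episode_days < 0:
            raise ConfigError("min_inter_episode_days must be non-negative")
        if not 0 < self.wear_hours_per_day <= 24:
            raise ConfigError("wear_hours_per_day must be in (0, 24]")
        if not 0 <= self.charging_hours_per_day < 24:
            raise ConfigError("charging_hours_per_day must be in [0, 24)")
        if self.wear_hours_per_day + self.charging_hours_per_day > 24:
            raise ConfigError("wear + charging hours must not exceed 24")
        for name in ("unreliable_fraction", "survey_compliance",
                     "baseline_major_p", "baseline_minor_p",
                     "episode_major_p", "episode_minor_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability, got {v}")
        mix = self.activity_mix
        if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1) > 1e-9:
            raise ConfigError("activity_mix must be 3 non-negative numbers summing to 1")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activity_mix"] = list(self.activity_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ActivityThresholds(**d["thresholds"])
        if "activity_mix" in d:
            d["activity_mix"] = tuple(d["activity_mix"])
        return cls(**d)


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return CohortConfig.from_dict(data)
    except TypeError as exc:  # unknown keys
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
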