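"""Heart-rate stream cleaning and daily statistics.

Samples are kept only when the watch was off its charger and the sensor
status read reliable — the same validity rule applied to accelerometry.
Valid samples are grouped by calendar day into mean, sample (n-1) standard
deviation and recording count; a "day of available data" is any calendar
day with at least one valid recording.  No physiological range filter is
applied beyond requiring positive bpm.

Streams are DataFrames with columns ``timestamp`` (datetime64), ``bpm``,
``charging`` and ``reliable``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

HR_COLUMNS = ["timestamp", "bpm", "charging", "reliable"]


@dataclass(frozen=True)
class PatientHeartRateSummary:
    """Per-patient roll-up over all valid recordings.

    ``mean_bpm``/``sd_bpm`` pool every valid recording; because pooling
    convention matters when days differ in recording count, the mean of
    daily means is also carried (``mean_of_daily_means``).
    """

    mean_bpm: float
    sd_bpm: float
    mean_of_daily_means: float
    days_available: int
    n_recordings: int


def filter_heart_rate(stream: pd.DataFrame) -> pd.DataFrame:
    """Keep samples with charging=False and reliable=True, order preserved."""
    mask = (~stream["charging"].to_numpy(bool)) & stream["reliable"].to_numpy(bool)
    return stream.loc[mask]


def daily_heart_rate(
    stream: pd.DataFrame, utc_offset_hours: float = 0.0
) -> pd.DataFrame:
    """Group a (filtered) stream by calendar day.

    Returns columns ``date``, ``mean_bpm``, ``sd_bpm`` (sample SD; 0 for a
    single-recording day) and ``n_recordings``.  Days with no valid sample
    simply do not appear.
    """
    if len(stream) == 0:
        return pd.DataFrame(columns=["date", "mean_bpm", "sd_bpm", "n_recordings"])
    offset = int(round(utc_offset_hours * 3600))
    ts = stream["timestamp"].to_numpy("datetime64[ms]").astype("int64") // 1000
    date = (((ts + offset) // 86400) * 86400).astype("datetime64[s]").astype(
        "datetime64[D]"
    )
    g = stream.assign(date=date).groupby("date", sort=True)["bpm"]
    out = g.agg(mean_bpm="mean", sd_bpm="std", n_recordings="count").reset_index()
    out["sd_bpm"] = out["sd_bpm"].fillna(0.0)  # single-recording days
    return out


def patient_heart_rate_summary(daily: pd.DataFrame) -> PatientHeartRateSummary:
    """Pool the daily table back into one per-patient row.

    The pooled mean and SD are reconstructed exactly from the per-day
    sufficient statistics (mean, sample SD, count), so they equal the mean
    and sample SD of the underlying valid recordings.
    """
    if len(daily) == 0:
        return PatientHeartRateSummary(math.nan, math.nan, math.nan, 0, 0)
    n = daily["n_recordings"].to_numpy(float)
    m = daily["mean_bpm"].to_numpy(float)
    sd = daily["sd_bpm"].to_numpy(float)
    total = n.sum()
    grand = float((n * m).sum() / total)
    ss = float(((n - 1) * sd**2 + n * (m - grand) ** 2).sum())
    pooled_sd = 0.0 if total <= 1 else math.sqrt(ss / (total - 1))
    return PatientHeartRateSummary(
        mean_bpm=grand,
        sd_bpm=pooled_sd,
        mean_of_daily_means=float(np.mean(m)),
        days_available=int(len(daily)),
        n_recordings=int(total),
    )
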