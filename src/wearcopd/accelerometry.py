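"""Tri-axial accelerometry: gravity removal, per-minute motion counts,
and sedentary / light / MVPA classification.

The processing chain mirrors the standard actigraphy recipe for raw
accelerometer streams recorded under a duty cycle:

1. keep only samples taken while the device was not charging and its
   sensor status was reliable;
2. estimate the gravity component per axis with a centred moving average
   (default 2 s window, reflected boundaries) inside each contiguous
   recording burst, and subtract it;
3. integrate the Euclidean magnitude of the residual motion vector over
   each calendar-aligned 60 s epoch (trapezoidal rule), rescaling to a
   per-minute rate when the epoch is only partially covered — this is the
   "area under the curve" motion summary in counts per minute;
4. classify each valid minute against fixed cut-points: < 50.92 counts/min
   is sedentary, > 305.36 counts/min is MVPA, anything else is light.

A minute is valid when at least half of the samples the device recorded in
it survive the charging/reliability filter (the duty cycle means most
minutes have either a full 60 s of samples or none at all).

Streams are pandas DataFrames with columns ``timestamp`` (datetime64),
``ax``, ``ay``, ``az`` (m/s^2), ``charging`` and ``reliable`` (bool).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .config import ActivityThresholds

ACCEL_COLUMNS = ["timestamp", "ax", "ay", "az", "charging", "reliable"]

SEDENTARY = "sedentary"
LIGHT = "light"
MVPA = "mvpa"
INVALID = "invalid"

#: minimum fraction of recorded samples in a minute that must be valid
MIN_VALID_FRACTION = 0.5


def filter_valid_samples(stream: pd.DataFrame) -> pd.DataFrame:
    """Keep samples recorded while not charging and flagged reliable."""
    mask = (~stream["charging"].to_numpy(bool)) & stream["reliable"].to_numpy(bool)
    return stream.loc[mask]


def split_bursts(timestamps: np.ndarray, sample_hz: float) -> list[slice]:
    """Slice a sorted timestamp array (seconds) into contiguous bursts.

    A gap longer than five nominal sample intervals starts a new burst;
    under the 2-in-10-minute duty cycle bursts are the 2-minute recording
    windows.
    """
    if len(timestamps) == 0:
        return []
    gap = 5.0 / sample_hz
    breaks = np.flatnonzero(np.diff(timestamps) > gap) + 1
    edges = np.concatenate(([0], breaks, [len(timestamps)]))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def remove_gravity(
    window: np.ndarray, sample_hz: float, window_seconds: float = 2.0
) -> np.ndarray:
    """Subtract a moving-average gravity estimate from an (n, 3) window.

    The gravity component is estimated per axis with a centred moving
    average (odd length, about ``window_seconds`` long, reflected
    boundaries); the residual is the motion component.  For a static
    window the residual is ~0; the filter is linear, so motion of
    superposed signals superposes.

    Raises ``ValueError`` for windows with fewer than 2 samples, which the
    caller should mark invalid.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of axis samples")
    n = window.shape[0]
    if n < 2:
        raise ValueError("gravity removal needs at least 2 samples")
    length = int(round(window_seconds * sample_hz))
    length = max(3, min(length | 1, n if n % 2 == 1 else n - 1))
    gravity = uniform_filter1d(window, size=length, axis=0, mode="reflect")
    return window - gravity


def motion_counts(
    timestamps: np.ndarray,
    magnitudes: np.ndarray,
    count_scale: float = 1.0,
    epoch_seconds: float = 60.0,
) -> float:
    """Area-under-the-curve motion summary for one epoch, as a per-minute rate.

    Trapezoidal integral of the motion magnitude over the samples' time
    span, rescaled to the full epoch length when the span covers only part
    of it.  ``count_scale`` converts (m/s^2)·s of integrated magnitude into
    counts.  Raises ``ValueError`` for fewer than two samples.
    """
    t = np.asarray(timestamps, dtype=float)
    m = np.asarray(magnitudes, dtype=float)
    if t.size < 2:
        raise ValueError("motion counts need at least 2 samples in the epoch")
    covered = t[-1] - t[0]
    if covered <= 0:
        raise ValueError("epoch samples must span positive time")
    auc = np.trapezoid(m, t)
    return float(count_scale * auc * (epoch_seconds / covered))


def classify_minute(counts: float, thresholds: ActivityThresholds) -> str:
    """Map a counts-per-minute value onto {sedentary, light, mvpa}.

    The cut-point inequalities are strict, so a minute landing exactly on
    a threshold is light.
    """
    if counts < 0:
        raise ValueError(f"counts must be non-negative, got {counts}")
    if counts < thresholds.sedentary_max:
        return SEDENTARY
    if counts > thresholds.mvpa_min:
        return MVPA
    return LIGHT


def minute_activity(
    stream: pd.DataFrame,
    sample_hz: float,
    thresholds: ActivityThresholds | None = None,
    count_scale: float = 1.0,
    gravity_window_seconds: float = 2.0,
    utc_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Full per-minute pipeline: filter, de-gravity, integrate, classify.

    Returns a DataFrame with one row per minute that contained any
    recorded sample: ``minute_start`` (datetime64), ``counts``,
    ``n_samples`` (valid samples), ``valid`` and ``activity_class``.
    Minutes where fewer than half of the recorded samples are valid, or
    with fewer than 2 valid samples, are marked invalid with class
    ``invalid`` and NaN counts.
    """
    if thresholds is None:
        thresholds = ActivityThresholds()
    offset = int(round(utc_offset_hours * 3600))
    ts_all = stream["timestamp"].to_numpy("datetime64[ms]").astype("int64") / 1000.0
    minute_all = np.floor((ts_all + offset) / 60.0).astype("int64")
    recorded_per_minute = pd.Series(minute_all).value_counts().sort_index()

    valid = filter_valid_samples(stream)
    ts = valid["timestamp"].to_numpy("datetime64[ms]").astype("int64") / 1000.0
    axes = valid[["ax", "ay", "az"]].to_numpy(float)

    mag = np.full(len(ts), np.nan)
    for sl in split_bursts(ts, sample_hz):
        seg = axes[sl]
        if seg.shape[0] < 2:
            continue
        motion = remove_gravity(seg, sample_hz, gravity_window_seconds)
        mag[sl] = np.linalg.norm(motion, axis=1)

    minute = np.floor((ts + offset) / 60.0).astype("int64")  # sorted with ts
    rows = []
    for m in recorded_per_minute.index:
        n_recorded = int(recorded_per_minute.loc[m])
        lo, hi = np.searchsorted(minute, [m, m + 1])
        in_min = lo + np.flatnonzero(~np.isnan(mag[lo:hi]))
        n_valid = int(in_min.size)
        ok = n_valid >= 2 and n_valid >= MIN_VALID_FRACTION * n_recorded
        if ok:
            counts = motion_counts(ts[in_min], mag[in_min], count_scale)
            cls = classify_minute(counts, thresholds)
        else:
            counts, cls = np.nan, INVALID
        rows.append((m, counts, n_valid, ok, cls))

    out = pd.DataFrame(
        rows, columns=["minute", "counts", "n_samples", "valid", "activity_class"]
    )
    # minute_start rendered back in UTC
    out["minute_start"] = (out["minute"] * 60 - offset).astype("datetime64[s]")
    return out[["minute_start", "counts", "n_samples", "valid", "activity_class"]]


def daily_activity_summary(
    minutes: pd.DataFrame, utc_offset_hours: float = 0.0
) -> pd.DataFrame:
    """Per-day percentage of valid minutes in each class.

    Percentages are taken over valid minutes only; a day whose minutes are
    all invalid is kept as a no-data row (``valid_minutes = 0``, NaN
    percentages).  For any day with at least one valid minute the three
    percentages sum to 100.
    """
    offset = int(round(utc_offset_hours * 3600))
    ts = minutes["minute_start"].to_numpy("datetime64[s]").astype("int64")
    local_day = ((ts + offset) // 86400).astype("int64")
    date = (local_day * 86400).astype("datetime64[s]").astype("datetime64[D]")
    df = minutes.assign(date=date)

    rows = []
    for day, grp in df.groupby("date", sort=True):
        v = grp[grp["valid"]]
        nv = len(v)
        if nv == 0:
            rows.append((day, np.nan, np.nan, np.nan, 0))
            continue
        counts = v["activity_class"].value_counts()
        rows.append(
            (
                day,
                100.0 * counts.get(SEDENTARY, 0) / nv,
                100.0 * counts.get(LIGHT, 0) / nv,
                100.0 * counts.get(MVPA, 0) / nv,
                nv,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["date", "pct_sedentary", "pct_light", "pct_mvpa", "valid_minutes"],
    )
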