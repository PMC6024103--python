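"""Daily symptom-diary scoring and exacerbation (AECOPD) episode detection.

The diary is the 8-item London COPD cohort daily questionnaire: three
*major* symptoms (dyspnea, sputum purulence, increased sputum volume) and
five *minor* symptoms (nasal discharge/congestion, wheeze, sore throat,
cough, fever), each answered yes/no.  The daily score weights each major
symptom 5 points and each minor symptom 1 point, so scores live in [0, 20].

An acute exacerbation of COPD (AECOPD) opens on the first day of a run of
two consecutive diary days with score strictly greater than 5, and resolves
on the last day of the first subsequent run of five consecutive diary days
with score exactly 0.  Days without a diary entry break both runs: the
rules demand *consecutive recorded* days, the conservative reading when
entries are missing.  Episodes for a patient never overlap; elevated scores
during an open episode extend it rather than starting a new one.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

MAJOR_SYMPTOMS = ("dyspnea", "sputum_purulence", "sputum_volume")
MINOR_SYMPTOMS = ("nasal", "wheeze", "sore_throat", "cough", "fever")
SYMPTOMS = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

MAJOR_WEIGHT = 5
MINOR_WEIGHT = 1
ONSET_SCORE_THRESHOLD = 5       # strictly greater-than qualifies
ONSET_RUN_DAYS = 2
RESOLUTION_RUN_DAYS = 5         # consecutive zero-score days


class DiaryError(ValueError):
    """Raised for malformed or inconsistent diary input."""


@dataclass(frozen=True)
class SymptomDiaryEntry:
    """One calendar day's eight binary symptom responses for one patient."""

    patient_id: str
    date: dt.date
    dyspnea: bool
    sputum_purulence: bool
    sputum_volume: bool
    nasal: bool
    wheeze: bool
    sore_throat: bool
    cough: bool
    fever: bool

    def __post_init__(self) -> None:
        for name in SYMPTOMS:
            v = getattr(self, name)
            if not isinstance(v, bool):
                raise DiaryError(f"symptom {name!r} must be boolean, got {v!r}")


@dataclass(frozen=True)
class DailyScore:
    date: dt.date
    score: int | None
    present: bool

    def __post_init__(self) -> None:
        if self.present and (self.score is None or not 0 <= self.score <= 20):
            raise DiaryError(f"present day needs a score in [0, 20], got {self.score}")
        if not self.present and self.score is not None:
            raise DiaryError("absent day must have no score")


@dataclass(frozen=True)
class ExacerbationEpisode:
    """A detected AECOPD interval; open episodes have no resolution date."""

    onset: dt.date
    resolution: dt.date | None
    resolved: bool

    @property
    def duration_days(self) -> int | None:
        """Inclusive onset-to-resolution length; None while still open."""
        if not self.resolved or self.resolution is None:
            return None
        return (self.resolution - self.onset).days + 1


def score_day(entry: SymptomDiaryEntry) -> DailyScore:
    """Score one diary entry: 5 points per major symptom, 1 per minor."""
    score = MAJOR_WEIGHT * sum(getattr(entry, s) for s in MAJOR_SYMPTOMS)
    score += MINOR_WEIGHT * sum(getattr(entry, s) for s in MINOR_SYMPTOMS)
    return DailyScore(date=entry.date, score=score, present=True)


def score_series(
    entries: Iterable[SymptomDiaryEntry],
    study_start: dt.date,
    study_end: dt.date,
) -> list[DailyScore]:
    """One :class:`DailyScore` per calendar day in [study_start, study_end].

    Days without an entry get ``present=False``.  Duplicate or
    out-of-range dates are errors.
    """
    if study_end < study_start:
        raise DiaryError("study_end precedes study_start")
    by_date: dict[dt.date, SymptomDiaryEntry] = {}
    for e in entries:
        if not study_start <= e.date <= study_end:
            raise DiaryError(f"entry date {e.date} outside study window")
        if e.date in by_date:
            raise DiaryError(f"duplicate diary entry for {e.date}")
        by_date[e.date] = e
    out = []
    day = study_start
    while day <= study_end:
        if day in by_date:
            out.append(score_day(by_date[day]))
        else:
            out.append(DailyScore(date=day, score=None, present=False))
        day += dt.timedelta(days=1)
    return out


def _check_ordered(scores: Sequence[DailyScore]) -> None:
    for a, b in zip(scores, scores[1:]):
        if b.date <= a.date:
            raise DiaryError("score series must be strictly chronological")


def detect_exacerbations(scores: Sequence[DailyScore]) -> list[ExacerbationEpisode]:
    """Run-length AECOPD detection over a chronological daily score series.

    Onset: first day of the first run of two consecutive present days with
    score > 5 while no episode is open.  Resolution: last day of the first
    run of five consecutive present days with score 0 after onset.  An
    absent day resets both run counters.  Calendar gaps between present
    days also break runs ("consecutive" is calendar-consecutive).
    """
    _check_ordered(scores)
    episodes: list[ExacerbationEpisode] = []
    open_onset: dt.date | None = None
    high_run_start: dt.date | None = None
    high_run = 0
    zero_run_start: dt.date | None = None
    zero_run = 0
    prev_present_date: dt.date | None = None

    for s in scores:
        contiguous = (
            prev_present_date is not None
            and s.present
            and (s.date - prev_present_date).days == 1
        )
        if not s.present:
            high_run = 0
            zero_run = 0
            continue
        if open_onset is None:
            if s.score > ONSET_SCORE_THRESHOLD:
                if contiguous and high_run > 0:
                    high_run += 1
                else:
                    high_run = 1
                    high_run_start = s.date
                if high_run >= ONSET_RUN_DAYS:
                    open_onset = high_run_start
                    high_run = 0
                    zero_run = 0
            else:
                high_run = 0
        else:
            if s.score == 0:
                if contiguous and zero_run > 0:
                    zero_run += 1
                else:
                    zero_run = 1
                    zero_run_start = s.date
                if zero_run >= RESOLUTION_RUN_DAYS:
                    episodes.append(
                        ExacerbationEpisode(
                            onset=open_onset, resolution=s.date, resolved=True
                        )
                    )
                    open_onset = None
                    zero_run = 0
                    high_run = 0
            else:
                zero_run = 0
        prev_present_date = s.date if s.present else prev_present_date

    if open_onset is not None:
        episodes.append(
            ExacerbationEpisode(onset=open_onset, resolution=None, resolved=False)
        )
    return episodes


def exacerbation_burden(
    scores: Sequence[DailyScore],
    episodes: Sequence[ExacerbationEpisode],
) -> float:
    """Fraction of the monitored span spent inside detected episodes.

    The monitored span runs from the first to the last present diary day,
    inclusive.  Open episodes contribute their days up to the end of the
    span.  Raises :class:`DiaryError` when no day is present (undefined).
    """
    present = [s.date for s in scores if s.present]
    if not present:
        raise DiaryError("exacerbation burden undefined: no present diary days")
    first, last = present[0], present[-1]
    span = (last - first).days + 1
    in_episode = 0
    for ep in episodes:
        start = max(ep.onset, first)
        end = min(ep.resolution if ep.resolved else last, last)
        if end >= start:
            in_episode += (end - start).days + 1
    return in_episode / span


def completion_rate(scores: Sequence[DailyScore]) -> float:
    """Percentage of study days with a completed diary entry."""
    if not scores:
        raise DiaryError("completion rate undefined for an empty study period")
    return 100.0 * sum(s.present for s in scores) / len(scores)


def mean_score(scores: Sequence[DailyScore]) -> tuple[float, float, int]:
    """Mean and sample SD of present daily scores, plus the day count.

    Single-day series get SD 0 by convention; returns (nan, nan, 0) when
    no day is present.
    """
    import math
    vals = [s.score for s in scores if s.present]
    n = len(vals)
    if n == 0:
        return (math.nan, math.nan, 0)
    m = sum(vals) / n
    sd = 0.0 if n == 1 else math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))
    return (m, sd, n)
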