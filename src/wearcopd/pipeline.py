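"""Stage runners and the end-to-end pipeline.

Each stage is a plain function over files so the command-line interface,
the analysis drivers and the tests share one code path:

    simulate -> score -> activity -> vitals -> summarize

A cohort directory holds one sub-directory per patient
(``patient_000/ ...``) with ``accel.csv``, ``hr.csv``, ``diary.jsonl``
and ``truth.json``, plus the cohort ``config.yaml``.  Stages write their
tables next to the inputs; ``run_pipeline`` finishes with a manifest
recording the config hash, seed and package version so reruns are
auditable (and, under a fixed seed, byte-identical).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from pathlib import Path

import pandas as pd

from . import __version__
from . import accelerometry, availability, diary, io, synthetic, vitals
from .config import CohortConfig, dump_config

log = logging.getLogger("wearcopd")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def patient_dir(root: Path, index: int) -> Path:
    return Path(root) / f"patient_{index:03d}"


def stage_simulate(config: CohortConfig, out: Path, accel_days: int | None = None) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config.yaml")
    for i in range(config.n_patients):
        pdir = patient_dir(out, i)
        pdir.mkdir(exist_ok=True)
        data = synthetic.generate_patient(config, i, accel_days=accel_days)
        io.write_stream(data["accel"], pdir / "accel.csv")
        io.write_stream(data["hr"], pdir / "hr.csv")
        io.write_diary(data["diary"], pdir / "diary.jsonl")
        io.write_json(synthetic.truth_dict(data["state"], config), pdir / "truth.json")
        log.info(
            "simulate: patient %d — %d accel, %d hr, %d diary records",
            i, len(data["accel"]), len(data["hr"]), len(data["diary"]),
        )


def stage_score(diary_path: Path, start: dt.date, end: dt.date, out: Path) -> None:
    """Score one diary and detect exacerbation episodes."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    entries = io.read_diary(diary_path)
    scores = diary.score_series(entries, start, end)
    episodes = diary.detect_exacerbations(scores)
    pd.DataFrame(
        {
            "date": [s.date.isoformat() for s in scores],
            "score": [s.score if s.present else "" for s in scores],
            "present": [s.present for s in scores],
        }
    ).to_csv(out / "scores.csv", index=False)
    pd.DataFrame(
        {
            "onset": [e.onset.isoformat() for e in episodes],
            "resolution": [e.resolution.isoformat() if e.resolved else "" for e in episodes],
            "duration_days": [e.duration_days if e.resolved else "" for e in episodes],
            "resolved": [e.resolved for e in episodes],
        }
    ).to_csv(out / "episodes.csv", index=False)
    log.info("score: %d entries, %d episodes", len(entries), len(episodes))


def stage_activity(accel_path: Path, config: CohortConfig, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stream = io.read_accel(accel_path)
    minutes = accelerometry.minute_activity(
        stream,
        sample_hz=config.accel_hz,
        thresholds=config.thresholds,
        count_scale=config.count_scale,
        gravity_window_seconds=config.gravity_window_seconds,
        utc_offset_hours=config.utc_offset_hours,
    )
    daily = accelerometry.daily_activity_summary(minutes, config.utc_offset_hours)
    minutes.to_csv(out / "minutes.csv", index=False)
    daily.to_csv(out / "activity_daily.csv", index=False)
    log.info("activity: %d minutes, %d days", len(minutes), len(daily))


def stage_vitals(hr_path: Path, config: CohortConfig, out: Path) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stream = io.read_hr(hr_path)
    daily = vitals.daily_heart_rate(
        vitals.filter_heart_rate(stream), config.utc_offset_hours
    )
    daily.to_csv(out / "hr_daily.csv", index=False)
    log.info("vitals: %d days of heart-rate data", len(daily))


def _read_scores(path: Path) -> list[diary.DailyScore]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        present = bool(row["present"])
        score = int(row["score"]) if present else None
        out.append(
            diary.DailyScore(
                date=dt.date.fromisoformat(row["date"]), score=score, present=present
            )
        )
    return out


def _read_episodes(path: Path) -> list[diary.ExacerbationEpisode]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        resolved = bool(row["resolved"])
        out.append(
            diary.ExacerbationEpisode(
                onset=dt.date.fromisoformat(row["onset"]),
                resolution=dt.date.fromisoformat(row["resolution"]) if resolved else None,
                resolved=resolved,
            )
        )
    return out


def stage_summarize(cohort_dir: Path, config: CohortConfig, out: Path) -> None:
    """Roll per-patient stage outputs into the cohort tables."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    all_episodes: list[diary.ExacerbationEpisode] = []
    burdens: list[float] = []
    for i in range(config.n_patients):
        pdir = patient_dir(cohort_dir, i)
        scores = _read_scores(pdir / "scores.csv")
        episodes = _read_episodes(pdir / "episodes.csv")
        hr_daily = pd.read_csv(pdir / "hr_daily.csv")
        act_daily = pd.read_csv(pdir / "activity_daily.csv")
        summaries.append(
            availability.patient_summary(
                f"P{i:03d}", scores, episodes, hr_daily, act_daily, config.study_days
            )
        )
        all_episodes.extend(episodes)
        if any(s.present for s in scores):
            burdens.append(diary.exacerbation_burden(scores, episodes))
    cohort = availability.cohort_summary(summaries)
    stats = availability.exacerbation_cohort_stats(all_episodes, burdens)
    availability.summaries_to_frame(summaries).to_csv(
        out / "patient_summary.csv", index=False
    )
    row = {**cohort.__dict__, **{f"exac_{k}": v for k, v in stats.__dict__.items()}}
    pd.DataFrame([row]).to_csv(out / "cohort_summary.csv", index=False)
    log.info(
        "summarize: %d patients, %d episodes (%d resolved)",
        cohort.n_patients, stats.n_episodes, stats.n_resolved,
    )


def run_pipeline(
    config: CohortConfig,
    out: Path,
    simulate: bool = True,
    accel_days: int | None = None,
) -> Path:
    """Run every stage over a cohort directory and write the manifest.

    With ``simulate=False`` the cohort directory must already contain the
    per-patient raw files.  Returns the manifest path.
    """
    out = Path(out)
    start = dt.date.fromisoformat(config.start_date)
    end = start + dt.timedelta(days=config.study_days - 1)
    stages: list[tuple[str, callable]] = []
    if simulate:
        stages.append(("simulate", lambda: stage_simulate(config, out, accel_days)))

    def per_patient() -> None:
        for i in range(config.n_patients):
            pdir = patient_dir(out, i)
            if not pdir.is_dir():
                raise FileNotFoundError(f"missing patient directory {pdir}")
            stage_score(pdir / "diary.jsonl", start, end, pdir)
            stage_activity(pdir / "accel.csv", config, pdir)
            stage_vitals(pdir / "hr.csv", config, pdir)

    stages.append(("score/activity/vitals", per_patient))
    stages.append(("summarize", lambda: stage_summarize(out, config, out)))

    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise StageError(f"[{name}] {exc}") from exc

    manifest = {
        "config_sha256": io.config_hash(config.to_dict()),
        "seed": config.seed,
        "n_patients": config.n_patients,
        "study_days": config.study_days,
        "wearcopd_version": __version__,
    }
    path = out / "manifest.json"
    io.write_json(manifest, path)
    return path
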