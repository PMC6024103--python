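#!/usr/bin/env python
"""Score the cohort's diaries and detect exacerbation episodes.

Applies the weighted symptom score (majors 5 points, minors 1) to every
diary day, then the run-length rules: onset after 2 consecutive days
above 5, resolution after 5 consecutive zero days.  Reports per-patient
completion, the episode count and duration statistics, and how many
patients spent more than 75% of their monitored time in exacerbation.

Reads scratch/cohort/ (run 01 first); writes results/episodes.csv and
results/diary_summary.csv.
"""

import datetime as dt
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

from wearcopd import diary, io
from wearcopd.availability import exacerbation_cohort_stats
from wearcopd.config import load_config
from wearcopd.pipeline import patient_dir, stage_score


def main() -> None:
    cfg = load_config(SCRATCH / "config.yaml")
    start = dt.date.fromisoformat(cfg.start_date)
    end = start + dt.timedelta(days=cfg.study_days - 1)
    RESULTS.mkdir(exist_ok=True)

    rows, ep_rows, burdens, all_eps = [], [], [], []
    for i in range(cfg.n_patients):
        pdir = patient_dir(SCRATCH, i)
        stage_score(pdir / "diary.jsonl", start, end, pdir)
        scores = diary.score_series(io.read_diary(pdir / "diary.jsonl"), start, end)
        eps = diary.detect_exacerbations(scores)
        mean, sd, days = diary.mean_score(scores)
        burden = diary.exacerbation_burden(scores, eps) if days else float("nan")
        rows.append({
            "patient_id": f"P{i:03d}",
            "mean_score": round(mean, 2),
            "sd_score": round(sd, 2),
            "days_completed": days,
            "completion_pct": round(diary.completion_rate(scores), 1),
            "n_episodes": len(eps),
            "burden": round(burden, 3),
        })
        burdens.append(burden)
        all_eps.extend(eps)
        for e in eps:
            ep_rows.append({
                "patient_id": f"P{i:03d}",
                "onset": e.onset,
                "resolution": e.resolution,
                "duration_days": e.duration_days,
                "resolved": e.resolved,
            })

    summary = pd.DataFrame(rows)
    episodes = pd.DataFrame(ep_rows)
    summary.to_csv(RESULTS / "diary_summary.csv", index=False)
    episodes.to_csv(RESULTS / "episodes.csv", index=False)

    stats = exacerbation_cohort_stats(all_eps, burdens)
    print(f"completion: mean {summary['completion_pct'].mean():.1f}% "
          f"(range {summary['completion_pct'].min():.1f}-"
          f"{summary['completion_pct'].max():.1f}%)")
    print(f"episodes detected: {stats.n_episodes} "
          f"({stats.n_resolved} resolved, mean duration "
          f"{stats.mean_duration_days:.1f} (SD {stats.sd_duration_days:.1f}) days)")
    print(f"patients in exacerbation >75% of monitored time: "
          f"{stats.n_patients_high_burden}/{cfg.n_patients}")


if __name__ == "__main__":
    sys.exit(main())
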