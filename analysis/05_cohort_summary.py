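#!/usr/bin/env python
"""Assemble the per-patient and cohort availability tables.

Rolls the per-patient stage outputs (scores, episodes, daily heart rate,
daily activity) into one row per patient and a cohort row, and
re-aggregates the published reference cohort's activity availability as
a cross-check of the cohort arithmetic.

Reads scratch/cohort/ (run 01-04 first); writes results/patient_summary.csv
and results/cohort_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

from wearcopd.availability import REFERENCE_COHORT, cohort_summary, round_report
from wearcopd.config import load_config
from wearcopd.pipeline import stage_summarize


def main() -> None:
    cfg = load_config(SCRATCH / "config.yaml")
    RESULTS.mkdir(exist_ok=True)
    stage_summarize(SCRATCH, cfg, RESULTS)
    patients = pd.read_csv(RESULTS / "patient_summary.csv")
    cohort = pd.read_csv(RESULTS / "cohort_summary.csv")
    print(patients.to_string(index=False))
    row = cohort.iloc[0]
    print(f"\ncohort: survey {row['survey_days_completed']:.1f} days completed, "
          f"hr {row['hr_mean']:.1f} bpm over {row['hr_days_available']:.1f} days, "
          f"activity {row['activity_days_available']:.1f} days "
          f"({int(row['n_patients_with_activity_data'])} patients with data)")

    ref = cohort_summary(REFERENCE_COHORT)
    print(f"reference cohort check: activity availability "
          f"{round_report(ref.activity_days_available)} days across "
          f"{ref.n_patients} patients, "
          f"{ref.n_patients_with_activity_data} with data")


if __name__ == "__main__":
    sys.exit(main())
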