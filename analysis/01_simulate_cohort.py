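#!/usr/bin/env python
"""Generate the synthetic study cohort.

Simulates 16 patients over 90 days under the default study conditions:
sensors duty-cycled 2-in-10 minutes, accelerometer at 20 Hz, heart rate
every 2 s, diaries completed ~72% of days.  Raw 20 Hz accelerometer
streams are written for the first 3 study days per patient (the per-day
generative structure is stationary, and full-length raw streams run to
hundreds of MB); diaries and heart rate cover the whole study.

Writes scratch/cohort/patient_XXX/{accel.csv,hr.csv,diary.jsonl,truth.json}.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"

from wearcopd.config import CohortConfig
from wearcopd.pipeline import stage_simulate

ACCEL_DAYS = 3


def main() -> None:
    cfg = CohortConfig(seed=20170101)
    stage_simulate(cfg, SCRATCH, accel_days=ACCEL_DAYS)
    n_files = sum(1 for _ in SCRATCH.rglob("*") if _.is_file())
    print(f"simulated {cfg.n_patients} patients x {cfg.study_days} days "
          f"(raw accel: first {ACCEL_DAYS} days/patient) -> {SCRATCH} "
          f"({n_files} files)")


if __name__ == "__main__":
    sys.exit(main())
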