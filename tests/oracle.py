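"""Brute-force reference detector for AECOPD run-length rules.

Deliberately independent of :func:`wearcopd.diary.detect_exacerbations`:
instead of a single forward pass with run counters, it repeatedly *scans*
for the next qualifying 2-day high pair and then for the next qualifying
5-day zero run, using explicit slices and date arithmetic.
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

from wearcopd.diary import DailyScore, ExacerbationEpisode


def _consecutive(days: Sequence[DailyScore]) -> bool:
    return all(
        b.present and (b.date - a.date) == dt.timedelta(days=1)
        for a, b in zip(days, days[1:])
    ) and (not days or days[0].present)


def bruteforce_detect(scores: Sequence[DailyScore]) -> list[ExacerbationEpisode]:
    episodes: list[ExacerbationEpisode] = []
    n = len(scores)
    i = 0
    while i < n:
        onset_idx = None
        for j in range(i, n - 1):
            pair = scores[j : j + 2]
            if _consecutive(pair) and all(s.score > 5 for s in pair):
                onset_idx = j
                break
        if onset_idx is None:
            break
        res_idx = None
        for k in range(onset_idx, n - 4):
            run = scores[k : k + 5]
            if _consecutive(run) and all(s.score == 0 for s in run):
                res_idx = k + 4
                break
        if res_idx is None:
            episodes.append(
                ExacerbationEpisode(
                    onset=scores[onset_idx].date, resolution=None, resolved=False
                )
            )
            break
        episodes.append(
            ExacerbationEpisode(
                onset=scores[onset_idx].date,
                resolution=scores[res_idx].date,
                resolved=True,
            )
        )
        i = res_idx + 1
    return episodes
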