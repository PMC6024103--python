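"""Readers and writers for the on-disk interchange formats.

Everything is plain text: comma-separated CSV with a header row and
ISO-8601 timestamps for sensor streams, JSON-lines for diaries (one
object per line with ``patient_id``, ``date`` and the eight boolean
symptom fields), YAML for configuration and JSON for the latent truth
and the run manifest.  Readers validate schemas and report offending
line numbers; writers produce files the same readers accept, so a
write-then-read round trip returns identical records.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accelerometry import ACCEL_COLUMNS
from .diary import SYMPTOMS, DiaryError, SymptomDiaryEntry
from .vitals import HR_COLUMNS

log = logging.getLogger("wearcopd")


class SchemaError(ValueError):
    """Raised when an input file violates its schema."""


def _read_stream(path: str | Path, columns: list[str], value_col: dict) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file without header") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        log.warning("%s: no data rows", path)
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             {**{"timestamp": "datetime64[ms]"}, **value_col,
                              "charging": bool, "reliable": bool}.items()})[columns]
    try:
        parsed = pd.to_datetime(df["timestamp"], format="ISO8601", utc=True)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable timestamp ({exc})") from exc
    df["timestamp"] = parsed.dt.tz_localize(None).astype("datetime64[ms]")
    for c, typ in value_col.items():
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-indexing
            raise SchemaError(f"{path}: non-numeric {c!r} on lines {lines}")
        df[c] = vals.astype(typ)
    for c in ("charging", "reliable"):
        col = df[c]
        if col.dtype != bool:
            ok = col.astype(str).str.lower().isin(["true", "false"])
            bad = np.flatnonzero(~ok.to_numpy())
            if bad.size:
                lines = [int(i) + 2 for i in bad[:5]]
                raise SchemaError(f"{path}: non-boolean {c!r} on lines {lines}")
            df[c] = col.astype(str).str.lower() == "true"
    ts = df["timestamp"].to_numpy()
    if np.any(np.diff(ts.astype("int64")) < 0):
        raise SchemaError(f"{path}: timestamps must be non-decreasing")
    return df[columns]


def read_accel(path: str | Path) -> pd.DataFrame:
    return _read_stream(path, ACCEL_COLUMNS, {"ax": float, "ay": float, "az": float})


def read_hr(path: str | Path) -> pd.DataFrame:
    df = _read_stream(path, HR_COLUMNS, {"bpm": float})
    if len(df) and (df["bpm"] <= 0).any():
        bad = [int(i) + 2 for i in np.flatnonzero((df["bpm"] <= 0).to_numpy())[:5]]
        raise SchemaError(f"{path}: non-positive bpm on lines {bad}")
    return df


def write_stream(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    ).str.slice(0, 23) + "Z"
    df.to_csv(path, index=False)


def read_diary(path: str | Path) -> list[SymptomDiaryEntry]:
    """Parse a JSONL diary; malformed lines are hard errors with line numbers."""
    path = Path(path)
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            try:
                entry = SymptomDiaryEntry(
                    patient_id=str(obj["patient_id"]),
                    date=dt.date.fromisoformat(obj["date"]),
                    **{s: obj[s] for s in SYMPTOMS},
                )
            except KeyError as exc:
                raise SchemaError(f"{path}:{lineno}: missing field {exc}") from exc
            except (DiaryError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
    if not entries:
        log.warning("%s: empty diary", path)
    return entries


def write_diary(entries: list[SymptomDiaryEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            obj = {"patient_id": e.patient_id, "date": e.date.isoformat()}
            obj.update({s: getattr(e, s) for s in SYMPTOMS})
            fh.write(json.dumps(obj) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(config_dict: dict) -> str:
    blob = yaml.safe_dump(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
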