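"""CSV schemas, validated table loading, and run manifests.

All files are comma-separated UTF-8 with a header row, "." decimal
separator, and empty fields for missing values. Ages are integer days of
life; within-day timestamps are seconds from the start of the recording
window.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("runwheel")


class SchemaError(ValueError):
    """A table failed schema validation; the message names the offending row."""


#: schema name -> (columns, dtypes for numeric coercion)
SCHEMAS: dict[str, list[str]] = {
    "events": ["animal_id", "age_day", "timestamp_s"],
    "daily": ["animal_id", "age_day", "distance_km", "time_h",
              "avg_speed_kmh", "max_speed_kmh", "censored", "censor_reason"],
    "weekly": ["animal_id", "age_day", "rotarod_s", "weight_g", "tremor", "splay"],
    "onsets": ["animal_id", "metric", "baseline_value", "baseline_day",
               "onset_age", "censored", "threshold_fraction"],
    "summaries": ["study_id", "n", "metric", "mean_onset", "sd_onset", "cv_percent"],
    "animals": ["animal_id", "genotype", "group", "study_id", "endpoint_age"],
}

_NUMERIC = {
    "events": ["age_day", "timestamp_s"],
    "daily": ["age_day", "distance_km", "time_h", "avg_speed_kmh", "max_speed_kmh"],
    "weekly": ["age_day", "rotarod_s", "weight_g", "tremor", "splay"],
    "onsets": ["baseline_value", "baseline_day", "onset_age", "threshold_fraction"],
    "summaries": ["n", "mean_onset", "sd_onset", "cv_percent"],
    "animals": ["endpoint_age"],
}

_NONNEGATIVE = {
    "events": ["timestamp_s"],
    "daily": ["distance_km", "time_h", "avg_speed_kmh", "max_speed_kmh"],
    "weekly": ["rotarod_s", "weight_g"],
    "summaries": ["cv_percent", "sd_onset"],
}


def _check_events_sorted(df: pd.DataFrame) -> None:
    for (animal, day), sub in df.groupby(["animal_id", "age_day"], sort=False):
        t = sub["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(sub.index[np.argmax(np.diff(t) <= 0) + 1])
            raise SchemaError(
                f"row {bad + 2}: timestamps for animal {animal} day {day} "
                "are not strictly increasing"
            )
        if t.size and (t[0] < 0 or t[-1] >= 86400):
            raise SchemaError(f"animal {animal} day {day}: timestamps outside [0, 86400)")


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming the offending column or row on
    missing columns, unparseable numerics, negative values where forbidden,
    or unsorted event timestamps. An empty file with a valid header returns
    an empty frame (with a logged warning).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing} for schema '{schema}'")
    if df.empty:
        log.warning("%s: empty %s table (header only)", path.name, schema)
    for col in _NUMERIC.get(schema, []):
        raw = df[col].replace("", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"row {row + 2}: cannot parse {col}={df[col][row]!r} as a number")
        df[col] = vals
    for col in _NONNEGATIVE.get(schema, []):
        neg = df[col] < 0
        if neg.any():
            row = int(neg.idxmax())
            raise SchemaError(f"row {row + 2}: negative {col} = {df[col][row]}")
    if "censored" in df.columns:
        df["censored"] = df["censored"].astype(str).str.lower().isin(("true", "1", "yes"))
    if schema == "events" and not df.empty:
        _check_events_sorted(df)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a table in the canonical column order for ``schema``."""
    cols = [c for c in SCHEMAS[schema] if c in df.columns]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=cols, float_format="%.6g")
    return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it bit-for-bit."""

    seed: int
    preset: str
    n_animals: int
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dict(vars(self))
        payload["timestamp"] = payload["timestamp"] or datetime.now(timezone.utc).isoformat()
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
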