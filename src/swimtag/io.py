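"""CSV/JSON/YAML dialects used by the pipeline.

The tag vendors' export formats are proprietary, so this package defines its
own plain-text dialects and validates headers strictly: a file whose header
disagrees with the documented dialect is rejected rather than silently
reinterpreted.  Timestamps are timezone-naive local time (day/night labels
use local clock hours).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cardio import HrRecord

logger = logging.getLogger("swimtag")

__all__ = [
    "read_oxygen_trace",
    "read_triaxial_csv",
    "read_flow_csv",
    "read_sentinel_csv",
    "read_logger_csv",
    "write_hr_records",
    "write_report",
    "read_report",
    "load_config",
]

OXYGEN_COLUMNS = ["time_s", "do_percent", "phase", "speed_mps"]
TRIAXIAL_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]
FLOW_COLUMNS = ["time_s", "speed_mps"]
SENTINEL_COLUMNS = ["fish_id", "timestamp", "treatment", "hr_bpm", "ext_accel_mg",
                    "var_mg2", "odba_ms2"]
LOGGER_COLUMNS = ["timestamp", "hr_bpm", "qi"]

CONFIG_KEYS = {"chamber_volume_l", "do_max_mg_l", "body_mass_kg",
               "speed_step_mps", "step_duration_min", "measure_duration_h"}


def _read_csv_strict(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match the documented "
            f"dialect {columns}"
        )
    return df


def read_oxygen_trace(path) -> pd.DataFrame:
    """Oxygen trace CSV: ``time_s,do_percent,phase,speed_mps``."""
    df = _read_csv_strict(path, OXYGEN_COLUMNS)
    bad = ~df["phase"].isin(["acclimation", "measure", "flush"])
    if bad.any():
        raise ValueError(f"{path}: unknown phase labels {sorted(df.loc[bad, 'phase'].unique())}")
    return df


def read_triaxial_csv(path) -> pd.DataFrame:
    """Triaxial CSV: ``time_s,ax_g,ay_g,az_g``."""
    return _read_csv_strict(path, TRIAXIAL_COLUMNS)


def read_flow_csv(path) -> pd.DataFrame:
    """Flow CSV: ``time_s,speed_mps``."""
    return _read_csv_strict(path, FLOW_COLUMNS)


def read_sentinel_csv(path) -> pd.DataFrame:
    """Sentinel telemetry CSV with one row per fish per epoch."""
    df = _read_csv_strict(path, SENTINEL_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_logger_csv(path) -> tuple[list[HrRecord], int]:
    """Logger-export heart-rate CSV: ``timestamp,hr_bpm,qi``.

    Malformed rows (unparseable timestamp/values, qi outside 0-3,
    non-positive HR, HR present on a QI3 row) are skipped with a warning;
    returns ``(records, n_skipped)``.
    """
    df = _read_csv_strict(path, LOGGER_COLUMNS)
    records: list[HrRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            ts = pd.Timestamp(row["timestamp"]).to_pydatetime()
            qi = int(row["qi"])
            hr = None if pd.isna(row["hr_bpm"]) else float(row["hr_bpm"])
            records.append(HrRecord(timestamp=ts, hr_bpm=hr, qi=qi, source="logger",
                                    review_flag=qi in (1, 2)))
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} malformed row(s)", stacklevel=2)
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    return records, skipped


def write_hr_records(records: list[HrRecord], path) -> None:
    """HR records CSV: ``timestamp,hr_bpm,qi,review_flag``."""
    pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in records],
            "hr_bpm": [r.hr_bpm for r in records],
            "qi": [r.qi for r in records],
            "review_flag": [r.review_flag for r in records],
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report, path, seed: int | None = None, config: dict | None = None) -> None:
    """JSON report with a provenance block; bytes are deterministic.

    Provenance records the package version, the seed and a SHA-256 of the
    configuration; no wall-clock fields, so identical inputs give identical
    files.
    """
    payload = _jsonable(report)
    cfg = _jsonable(config or {})
    provenance = {
        "package": "swimtag",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
    }
    doc = {"provenance": provenance, "report": payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    for key in ("provenance", "report"):
        if key not in doc:
            raise ValueError(f"{path}: missing {key!r} block")
    return doc


def load_config(path) -> dict:
    """Respirometry config YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for k, v in raw.items():
        if not isinstance(v, (int, float)) or v <= 0:
            raise ValueError(f"{path}: {k} must be a positive number")
    return raw
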