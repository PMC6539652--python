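"""CSV/YAML readers and writers for the pipeline's interchange formats.

Raw recordings travel as columnar CSV (timestamp_iso8601, ax_g, ay_g,
az_g, status) with a sidecar YAML header carrying sample rate and dynamic
range; epoch series, cut-point tables, confusion charts and sub-band
histograms as plain CSV. Every writer prepends a provenance comment header
(config hash, seed, package version). Binary device formats (gt3x, CWA)
are out of scope; `register_raw_reader` lets callers plug in adapters that
return a RawRecording.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .recording import EpochSeries, RawRecording

_RAW_READERS: dict[str, Callable[[str], RawRecording]] = {}


def register_raw_reader(suffix: str, reader: Callable[[str], RawRecording]) -> None:
    """Register an adapter for a device file format (e.g. '.gt3x')."""
    _RAW_READERS[suffix.lower()] = reader


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return (
        f"# accelband v{__version__}\n"
        f"# config_sha256: {cfg_hash}\n"
        f"# seed: {seed}\n"
    )


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_raw_csv(recording: RawRecording, path: str | Path,
                  config: dict | None = None, seed: int | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp_iso8601": recording.times.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "ax_g": recording.samples[:, 0],
            "ay_g": recording.samples[:, 1],
            "az_g": recording.samples[:, 2],
            "status": np.where(recording.status == 1, "idle", "active"),
        }
    )
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, index=False, float_format="%.6f")
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {"sample_rate": recording.sample_rate, "dynamic_range": recording.dynamic_range},
            fh,
        )


def read_raw_csv(path: str | Path) -> RawRecording:
    """Parse a raw-acceleration CSV plus its sidecar YAML header.

    Validates strictly monotone, evenly spaced timestamps against the
    declared sample rate (1% tolerance); malformed or gapped rows raise
    with the first offending line number.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _RAW_READERS:
        return _RAW_READERS[suffix](str(path))
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar header {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    rate = float(meta["sample_rate"])
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=header_lines)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    required = {"timestamp_iso8601", "ax_g", "ay_g", "az_g", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty recording")
    for col in ("ax_g", "ay_g", "az_g"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.nonzero(bad.values)[0][0]) + header_lines + 2
            raise ValueError(f"{path}: malformed value in {col} at line {line}")
    times = pd.to_datetime(df["timestamp_iso8601"])
    dt = times.diff().dt.total_seconds().values[1:]
    expected = 1.0 / rate
    bad = (dt <= 0) | (np.abs(dt - expected) > 0.01 * expected)
    if bad.any():
        line = int(np.nonzero(bad)[0][0]) + header_lines + 3
        raise ValueError(
            f"{path}: timestamp gap or declared-rate mismatch at line {line}"
        )
    samples = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    status = (df["status"].astype(str).str.strip() == "idle").to_numpy().astype(np.uint8)
    return RawRecording(
        start_time=times.iloc[0],
        sample_rate=rate,
        samples=samples,
        dynamic_range=float(meta.get("dynamic_range", 6.0)),
        status=status,
    )


def write_epochs_csv(series: EpochSeries, path: str | Path,
                     config: dict | None = None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        series.to_frame().to_csv(fh, index=False)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    """Read any of the pipeline's CSV outputs, skipping provenance comments."""
    return pd.read_csv(path, comment="#")


def write_table_csv(df: pd.DataFrame, path: str | Path, *, index: bool = False,
                    config: dict | None = None, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, index=index)


# ---------------------------------------------------------------------------
# Pipeline configuration

_CONFIG_SCHEMA: dict[str, type | tuple] = {
    "variants": list,
    "epoch_lengths": list,
    "seed": int,
    "n_subjects_lab": int,
    "n_subjects_freeliving": int,
    "subject_cv": (int, float),
    "n_days": int,
    "age_groups": list,
    "vo2_noise_rel": (int, float),
    "signal_noise_sd": (int, float),
    "smoothing": (int, float),
    "min_wear_hours": (int, float),
    "window": list,
    "epoch_length": (int, float),
    "out_dir": str,
}

DEFAULT_CONFIG: dict = {
    "variants": ["ag_original", "bp4hz", "bp10hz", "hp_only"],
    "epoch_lengths": [1, 3, 10, 60],
    "epoch_length": 3,
    "seed": 0,
    "n_subjects_lab": 10,  # calibration group size, as in the lab protocol
    "n_subjects_freeliving": 2,  # cohort scaled down to desk size
    "subject_cv": 0.10,  # between-subject output variability (lognormal sd)
    "n_days": 7,
    "age_groups": ["child", "adult"],
    "vo2_noise_rel": 0.02,
    "signal_noise_sd": 0.01,
    "smoothing": 0.1,
    "min_wear_hours": 12.0,
    "window": ["06:00", "23:00"],
    "out_dir": "accelband_out",
}


def validate_config(config: dict | None) -> dict:
    """Merge user config over defaults; unknown keys or wrong types raise."""
    merged = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        if not isinstance(value, _CONFIG_SCHEMA[key]):
            raise ValueError(f"config key {key!r} has wrong type {type(value).__name__}")
        merged[key] = value
    return merged


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return validate_config(None)
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})
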