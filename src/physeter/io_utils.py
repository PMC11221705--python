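"""Versioned CSV / WAV / YAML I/O and bundled example data.

Every CSV written by the package carries a one-line schema header
(``# physeter-csv v<N> kind=<kind>``); readers verify both the version and
the kind, so schema drift fails loudly instead of silently misparsing.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .binning import Deployment

__all__ = [
    "SCHEMA_VERSION",
    "write_csv",
    "read_csv",
    "write_wav",
    "read_wav",
    "load_config",
    "validate_keys",
    "load_deployments",
    "sha256_of",
]

SCHEMA_VERSION = 1
_HEADER_RE = re.compile(r"^# physeter-csv v(\d+) kind=([\w.-]+)\s*$")


def write_csv(df: pd.DataFrame, path, kind: str, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# physeter-csv v{SCHEMA_VERSION} kind={kind}\n")
        df.to_csv(fh, index=index)
    return path


def read_csv(path, kind: str, **kwargs) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    m = _HEADER_RE.match(header)
    if not m:
        raise ValueError(f"{path}: missing schema header")
    version, found_kind = int(m.group(1)), m.group(2)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version {version}")
    if found_kind != kind:
        raise ValueError(f"{path}: expected kind={kind!r}, found {found_kind!r}")
    return pd.read_csv(path, skiprows=1, **kwargs)


def write_wav(path, waveform: np.ndarray, fs_hz: float) -> Path:
    """Write float32 WAV (amplitudes kept as-is; no rescaling)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(fs_hz), np.asarray(waveform, dtype=np.float32))
    return path


def read_wav(path) -> tuple[float, np.ndarray]:
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    return float(fs), data


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def validate_keys(cfg: dict, allowed: set[str], context: str = "config") -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")


def load_deployments() -> list[Deployment]:
    """Example deployment metadata bundled with the package (a multi-year
    GOA/BSAI hydrophone network; dates MM/DD/YY)."""
    ref = importlib.resources.files("physeter").joinpath("data/deployments_goa_bsai.csv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    out = []
    for _, row in df.iterrows():
        duty = None
        if not pd.isna(row.get("duty_record_min")):
            duty = (int(row["duty_record_min"]), int(row["duty_interval_min"]))
        out.append(Deployment(row["site"], row["start_date"], row["end_date"], duty))
    return out


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
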