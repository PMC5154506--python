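"""Reading and writing the pipeline's delimited-text formats."""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import RESPONSE_COLUMNS, validate_response_table

__all__ = [
    "read_response_table",
    "write_response_table",
    "read_config",
    "write_manifest",
]

_DTYPES = {
    "subject": str,
    "condition": str,
    "vis_dist": float,
    "aud_dist": float,
    "resp_vis": float,
    "resp_aud": float,
    "rep": "Int64",
}


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Read a trial-level response CSV and validate its layout.

    Empty cells denote fields that do not apply to a condition (e.g. no
    visual stimulus on an auditory-only trial).  Malformed numeric cells
    raise a ValueError naming the file line.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in RESPONSE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = pd.DataFrame()
    for col, dtype in _DTYPES.items():
        if dtype is str:
            out[col] = raw[col]
            continue
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in np.flatnonzero(bad)][:5]
            raise ValueError(f"{path}: unparseable {col!r} at line(s) {lines}")
        out[col] = converted
    out["rep"] = out["rep"].astype("Int64")
    return validate_response_table(out)


def write_response_table(data: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as CSV at full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, index=False, float_format=None)


def read_config(path: str | Path) -> dict:
    """Load a plain-text key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    return cfg


def _package_version() -> str:
    try:
        return version("avcausal")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Record the exact configuration and code version next to the outputs.

    Deliberately excludes wall-clock time so identical runs produce
    byte-identical manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "avcausal", "version": _package_version(), "config": config}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
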