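"""Reading and writing recording files and run configurations.

A recording file is plain delimited text: ``#``-prefixed ``key=value``
header lines (sampling rate, subject, condition, ...) followed by one CSV
row per sample with columns

    time_s, lh, lv, lt, rh, rv, rt, ax, ay, az, b_tesla

(left/right eye horizontal, vertical, torsional position in degrees; head
accelerometer in g units; magnetometer in Tesla).  External datasets with a
different layout are adapted through a column-mapping dict
``{schema_name: file_column}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import MappingError, SchemaError

RECORDING_COLUMNS = ["time_s", "lh", "lv", "lt", "rh", "rv", "rt", "ax", "ay", "az", "b_tesla"]
#: Minimum columns the analysis pipeline needs.
REQUIRED_COLUMNS = ["time_s", "lh", "rh", "b_tesla"]


@dataclass
class Recording:
    """One trial's time-aligned channels plus metadata."""

    data: pd.DataFrame
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    def cyclopean_horizontal(self) -> np.ndarray:
        return 0.5 * (self.data["lh"].to_numpy() + self.data["rh"].to_numpy())


def write_recording(path, rec: Recording) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        for key in sorted(rec.meta):
            fh.write(f"# {key}={rec.meta[key]}\n")
        rec.data.to_csv(fh, index=False, float_format="%.6f")


def read_recording(path, column_map: Optional[dict] = None) -> Recording:
    """Read a recording file, optionally adapting foreign column names.

    ``column_map`` maps schema names (``lh``, ``b_tesla``, ...) to the
    columns actually present in the file.  Required columns that can be
    matched neither directly nor through the map raise
    :class:`MappingError` listing every missing name.
    """
    path = Path(path)
    meta: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip)
    if column_map:
        rename = {src: dst for dst, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MappingError(
            f"recording {path.name} is missing required columns: {', '.join(missing)}"
        )
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    df = df[RECORDING_COLUMNS]
    fs = float(meta.get("fs", 1.0 / float(np.median(np.diff(df["time_s"])))))
    return Recording(data=df, fs=fs, meta=meta)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def load_yaml(path) -> dict:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return obj


def dump_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True, default_flow_style=False)
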