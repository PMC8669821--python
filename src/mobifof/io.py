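"""Delimited-file I/O for recordings, event tables and feature tables.

Recordings are CSV with columns ``time_s, acc_x, acc_y, acc_z`` (m/s^2)
and ``gyr_x, gyr_y, gyr_z`` (deg/s), plus a JSON sidecar carrying sample
rate, sensor site, axis map and any lab segment markers.  Event tables
mirror the ground-truth timeline layout (``category, start_s, end_s,
value``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import IMURecording


def write_recording(rec: IMURecording, csv_path, meta_path=None) -> None:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    df = pd.DataFrame({
        "time_s": rec.time,
        "acc_x": rec.acc[:, 0], "acc_y": rec.acc[:, 1], "acc_z": rec.acc[:, 2],
        "gyr_x": rec.gyro[:, 0], "gyr_y": rec.gyro[:, 1], "gyr_z": rec.gyro[:, 2],
    })
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "sample_rate": rec.sample_rate,
        "sensor_site": rec.sensor_site,
        "start_time": rec.start_time,
        "axis_convention": rec.axis_convention,
        "markers": {k: list(v) for k, v in rec.markers.items()},
    }
    meta_path.write_text(json.dumps(meta, indent=2))


def read_recording(csv_path, meta_path=None) -> IMURecording:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    df = pd.read_csv(csv_path)
    meta = json.loads(meta_path.read_text())
    return IMURecording(
        sample_rate=float(meta["sample_rate"]),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
        sensor_site=meta.get("sensor_site", "lower_back"),
        start_time=float(meta.get("start_time", 0.0)),
        axis_convention=meta["axis_convention"],
        markers={k: tuple(v) for k, v in meta.get("markers", {}).items()},
    )


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)
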