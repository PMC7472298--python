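"""CSV/JSON persistence for swings and datasets.

Layout (one directory per swing):

    swing_dir/
      wrist.csv, head.csv, waist.csv   # time_s,acc_x_g,...,gyro_z_dps
      clubhead.csv                     # time_s,ball_coord_m,speed_mps
      labels.json                      # dividing points + subject/club

A dataset manifest (``manifest.json``) lists swing directories relative to
its own location.  All floats are written with 12 significant digits so a
write/read round trip preserves values to well under 1e-9 and a second
write is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TimeError
from .swingdata import (
    PLACEMENTS,
    ClubheadTrack,
    DividingPoints,
    ImuRecording,
    SwingSet,
)

_IMU_COLUMNS = [
    "time_s",
    "acc_x_g",
    "acc_y_g",
    "acc_z_g",
    "gyro_x_dps",
    "gyro_y_dps",
    "gyro_z_dps",
]
_TRACK_COLUMNS = ["time_s", "ball_coord_m", "speed_mps"]
_FLOAT_FMT = "%.12g"


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def read_imu_csv(path, placement: str, sample_rate_hz: float = 200.0) -> ImuRecording:
    path = Path(path)
    df = _read_csv(path, _IMU_COLUMNS)
    t = df["time_s"].to_numpy(float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise TimeError(f"{path.name}: non-monotone time column")
    acc = df[["acc_x_g", "acc_y_g", "acc_z_g"]].to_numpy(float).T
    gyro = df[["gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]].to_numpy(float).T
    return ImuRecording(placement, t, acc, gyro, sample_rate_hz=sample_rate_hz)


def write_imu_csv(rec: ImuRecording, path) -> None:
    df = pd.DataFrame(
        dict(zip(_IMU_COLUMNS, [rec.t, *rec.acc, *rec.gyro])),
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_track_csv(path) -> ClubheadTrack:
    path = Path(path)
    df = _read_csv(path, _TRACK_COLUMNS)
    t = df["time_s"].to_numpy(float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise TimeError(f"{path.name}: non-monotone time column")
    return ClubheadTrack(t, df["ball_coord_m"].to_numpy(float), df["speed_mps"].to_numpy(float))


def write_track_csv(track: ClubheadTrack, path) -> None:
    df = pd.DataFrame(
        dict(zip(_TRACK_COLUMNS, [track.t, track.ball_coord, track.speed]))
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels_json(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("add_s", "bst_s", "imp_s", "fin_s", "subject_id", "club"):
        if key not in data:
            raise SchemaError(f"labels.json: missing key {key!r}")
    return data


def write_labels_json(points: DividingPoints, subject_id: str, club: str, path) -> None:
    data = {
        "add_s": points.add_s,
        "bst_s": points.bst_s,
        "imp_s": points.imp_s,
        "fin_s": points.fin_s,
        "subject_id": subject_id,
        "club": club,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_swing_csv(swing: SwingSet, swing_dir) -> None:
    """Write one swing (IMU CSVs per placement, clubhead CSV, labels JSON)."""
    swing_dir = Path(swing_dir)
    swing_dir.mkdir(parents=True, exist_ok=True)
    for placement, rec in swing.recordings.items():
        write_imu_csv(rec, swing_dir / f"{placement}.csv")
    write_track_csv(swing.track, swing_dir / "clubhead.csv")
    write_labels_json(swing.truth, swing.subject_id, swing.club, swing_dir / "labels.json")


def read_swing_csv(swing_dir, sample_rate_hz: float = 200.0) -> SwingSet:
    """Read one swing directory back into a :class:`SwingSet`."""
    swing_dir = Path(swing_dir)
    labels = read_labels_json(swing_dir / "labels.json")
    recordings: Dict[str, ImuRecording] = {}
    for placement in PLACEMENTS:
        p = swing_dir / f"{placement}.csv"
        if p.exists():
            recordings[placement] = read_imu_csv(p, placement, sample_rate_hz)
    if not recordings:
        raise SchemaError(f"{swing_dir}: no placement CSVs found")
    track = read_track_csv(swing_dir / "clubhead.csv")
    truth = DividingPoints(
        labels["add_s"], labels["bst_s"], labels["imp_s"], labels["fin_s"]
    )
    return SwingSet(labels["subject_id"], labels["club"], recordings, track, truth)


def write_dataset(swings: Sequence[SwingSet], out_dir) -> Path:
    """Write a dataset: one numbered directory per swing plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, swing in enumerate(swings):
        name = f"swing_{i:04d}"
        write_swing_csv(swing, out_dir / name)
        entries.append(
            {
                "dir": name,
                "subject_id": swing.subject_id,
                "club": swing.club,
                "placements": sorted(swing.recordings),
            }
        )
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"swings": entries}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_dataset(manifest_path) -> List[SwingSet]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "swings" not in manifest:
        raise SchemaError("manifest.json: missing 'swings' key")
    base = manifest_path.parent
    return [read_swing_csv(base / entry["dir"]) for entry in manifest["swings"]]
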