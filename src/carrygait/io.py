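"""On-disk interchange formats and in-memory containers for recordings and features.

All formats are plain text: CSV (RFC-4180, header row) for time series and
feature matrices, JSON for metadata, events, conditions, configs and results.
Floats are written with 10 significant digits, so round-trips are exact to
better than 1e-9 relative.

Channel naming
--------------
Kinematic channels follow the grammar ``<joint>|<plane>``.  The 22-joint
vocabulary mirrors a full-body 23-segment/22-joint inertial motion-capture
model: six spine/neck joints (L5-S1, L4-L3, L1-T12, T9-T8, T1-C7, C1-head)
and, per side, T4-shoulder, shoulder, elbow, wrist, hip, knee, ankle and
ball of the foot.  Each joint carries three angle planes, giving the 66
channels.  This joint list is a convention of this package, reconstructed
from the sensor system's documented biomechanical model.

Time is stored as seconds from trial start (t0 = 0); heel-strike events and
both sensor streams share this trial clock, so EMG step windows are located
by time rather than sample index and no resampling is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "KINEMATIC_FS",
    "EMG_FS",
    "JOINTS",
    "KINEMATIC_CHANNELS",
    "EMG_CHANNELS",
    "KinematicRecording",
    "EMGRecording",
    "TrialRecord",
    "write_trial",
    "read_trial",
    "write_feature_matrix",
    "read_feature_matrix",
]

KINEMATIC_FS = 240.0  # Hz, inertial motion-capture output rate
EMG_FS = 2148.0  # Hz, surface-EMG sampling rate

_SPINE_JOINTS = ("L5-S1", "L4-L3", "L1-T12", "T9-T8", "T1-C7", "C1-head")
_SIDED_JOINTS = (
    "T4-shoulder",
    "shoulder",
    "elbow",
    "wrist",
    "hip",
    "knee",
    "ankle",
    "ball of foot",
)

#: The 22 joints, canonical order: spine/neck, then right side, then left side.
JOINTS: tuple = _SPINE_JOINTS + tuple(
    f"{side} {j}" for side in ("right", "left") for j in _SIDED_JOINTS
)

_SPINE_PLANES = ("lateral bending", "axial bending", "flexion/extension")
_ARM_DISTAL_PLANES = ("pronation/supination", "ulnar/radial deviation", "flexion/extension")
_BALL_PLANES = ("abduction/adduction", "internal/external rotation", "flexion/extension")


def _planes(joint: str) -> tuple:
    if joint in _SPINE_JOINTS:
        return _SPINE_PLANES
    if joint.endswith(("elbow", "wrist")):
        return _ARM_DISTAL_PLANES
    return _BALL_PLANES


#: The 66 kinematic channel names, ``<joint>|<plane>``, canonical order.
KINEMATIC_CHANNELS: tuple = tuple(
    f"{joint}|{plane}" for joint in JOINTS for plane in _planes(joint)
)
assert len(KINEMATIC_CHANNELS) == 66

EMG_CHANNELS = ("left_erector_spinae", "right_erector_spinae")

_FLOAT_FMT = "%.10g"


@dataclass
class KinematicRecording:
    """66 joint-angle series (degrees) plus timestamped heel-strike events.

    ``data`` has shape (n_samples, 66) with columns in ``channel_names``
    order; ``heel_strikes`` is a list of ``(time_s, side)`` with side in
    {"L", "R"}, times strictly increasing within the recording span.
    """

    data: np.ndarray
    heel_strikes: list
    fs: float = KINEMATIC_FS
    t0: float = 0.0
    channel_names: tuple = KINEMATIC_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 66:
            raise ValueError(
                f"kinematic recording must have exactly 66 channels, "
                f"got {self.data.shape[1] if self.data.ndim == 2 else self.data.shape}"
            )
        if len(self.channel_names) != 66:
            raise ValueError("expected 66 channel names")
        times = [t for t, _ in self.heel_strikes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("heel-strike times must be strictly increasing")
        t_end = self.t0 + self.data.shape[0] / self.fs
        if times and (times[0] < self.t0 or times[-1] > t_end):
            raise ValueError("heel-strike events outside the recording span")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[0]) / self.fs

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs


@dataclass
class EMGRecording:
    """Two raw EMG series (arbitrary units): left and right erector spinae."""

    data: np.ndarray
    fs: float = EMG_FS
    t0: float = 0.0
    role: str = "trial"  # "trial" or "mvc"
    channel_names: tuple = EMG_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 2:
            raise ValueError(
                f"EMG recording must have exactly 2 channels, "
                f"got {self.data.shape[1] if self.data.ndim == 2 else self.data.shape}"
            )
        if self.fs <= 900.0:
            raise ValueError("EMG sampling rate must exceed 900 Hz (2 x 450 Hz band edge)")
        if self.role not in ("trial", "mvc"):
            raise ValueError(f"unknown EMG role: {self.role!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[0]) / self.fs

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs


@dataclass
class TrialRecord:
    """One trial of one participant; either sensor stream may be MISSING (None)."""

    participant_id: str
    condition_id: str
    kinematics: Optional[KinematicRecording]
    emg: Optional[EMGRecording]

    def __post_init__(self):
        if self.kinematics is None and self.emg is None:
            raise ValueError("at most one sensor system may be missing per trial")


def _write_series_csv(path: Path, times: np.ndarray, data: np.ndarray, names) -> None:
    df = pd.DataFrame(data, columns=list(names))
    df.insert(0, "time_s", times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_series_csv(path: Path, expected_names, kind: str) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns[1:]) != list(expected_names):
        raise ValueError(
            f"{kind} file {path} has {len(df.columns) - 1} channels; "
            f"expected {len(expected_names)} with the canonical names"
        )
    return df.iloc[:, 1:].to_numpy(dtype=float)


def write_trial(record: TrialRecord, path) -> None:
    """Write a trial as a directory: meta.json (+ kinematics.csv, emg.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema": "carrygait.trial",
        "version": 1,
        "participant_id": record.participant_id,
        "condition_id": record.condition_id,
        "kinematics": None,
        "emg": None,
    }
    if record.kinematics is not None:
        k = record.kinematics
        meta["kinematics"] = {
            "fs": k.fs,
            "t0": k.t0,
            "heel_strikes": [[float(t), s] for t, s in k.heel_strikes],
        }
        _write_series_csv(path / "kinematics.csv", k.times, k.data, k.channel_names)
    if record.emg is not None:
        e = record.emg
        meta["emg"] = {"fs": e.fs, "t0": e.t0, "role": e.role}
        _write_series_csv(path / "emg.csv", e.times, e.data, e.channel_names)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_trial(path) -> TrialRecord:
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed meta.json in {path}: {err}") from err
    if meta.get("schema") != "carrygait.trial":
        raise ValueError(f"{path}/meta.json is not a carrygait trial document")
    kin = None
    if meta["kinematics"] is not None:
        m = meta["kinematics"]
        data = _read_series_csv(path / "kinematics.csv", KINEMATIC_CHANNELS, "kinematics")
        kin = KinematicRecording(
            data,
            [(float(t), s) for t, s in m["heel_strikes"]],
            fs=float(m["fs"]),
            t0=float(m["t0"]),
        )
    emg = None
    if meta["emg"] is not None:
        m = meta["emg"]
        data = _read_series_csv(path / "emg.csv", EMG_CHANNELS, "EMG")
        emg = EMGRecording(data, fs=float(m["fs"]), t0=float(m["t0"]), role=m["role"])
    return TrialRecord(meta["participant_id"], meta["condition_id"], kin, emg)


def write_feature_matrix(table: pd.DataFrame, path) -> None:
    """Write a per-trial feature matrix (metadata + named feature columns) as CSV."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_matrix(path, expected_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        raise ValueError("duplicate feature names in header")
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ValueError(
            "feature matrix header does not match the expected schema "
            f"({len(df.columns)} columns vs {len(list(expected_columns))} expected)"
        )
    return df
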