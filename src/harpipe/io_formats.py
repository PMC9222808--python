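"""Readers and writers for raw inertial sensor logs and feature tables.

Two raw dialects are supported:

* ``shoaib`` — a canonical wide CSV for two-device (pocket + wrist)
  accelerometer + gyroscope recordings at 50 Hz.  Columns::

      subject,activity,t_index,pocket.accelerometer.x,...,wrist.gyroscope.z

  The original distribution of this style of dataset does not fix a file
  grammar, so this package defines one and emits it from the simulator.
* ``wisdm`` — the WISDM v1 raw line grammar
  ``user,activity,timestamp,x,y,z;`` (single pocket accelerometer, 20 Hz).

Feature tables are plain CSV with one row per window: a ``label`` column, a
``subject`` column, and ``F``-numbered feature columns prefixed by their
stream name.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "Recording",
    "FeatureRecord",
    "read_raw_recording",
    "write_raw_recording",
    "write_feature_table",
    "read_feature_table",
    "SHOAIB_STREAM_COLUMNS",
    "WISDM_ACTIVITIES",
]

DEVICE_POSITIONS = ("pocket", "wrist")
SENSOR_KINDS = ("accelerometer", "gyroscope", "body_accel", "gravity_accel")

#: column order of the canonical two-device CSV dialect
SHOAIB_STREAM_COLUMNS = [
    f"{device}.{sensor}.{axis}"
    for device in ("pocket", "wrist")
    for sensor in ("accelerometer", "gyroscope")
    for axis in ("x", "y", "z")
]

#: label vocabulary of the WISDM v1 raw files
WISDM_ACTIVITIES = frozenset(
    {"Walking", "Jogging", "Upstairs", "Downstairs", "Sitting", "Standing"}
)


@dataclass
class SensorStream:
    """One tri-axial time series from a single sensor on a single device.

    Parameters
    ----------
    device_position : {"pocket", "wrist"}
    sensor_kind : {"accelerometer", "gyroscope", "body_accel", "gravity_accel"}
    rate_hz : float
        Sampling rate in Hz; sample timestamps are implied by index / rate.
    samples : (n, 3) ndarray
        x, y, z values in m/s^2 (accelerometer family) or rad/s (gyroscope).
    labels : (n,) array of str
        Per-sample activity name.
    subject_id : str
    """

    device_position: str
    sensor_kind: str
    rate_hz: float
    samples: np.ndarray
    labels: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        if self.device_position not in DEVICE_POSITIONS:
            raise ValueError(f"unknown device position {self.device_position!r}")
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor kind {self.sensor_kind!r}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.samples):
            raise ValueError("labels and samples must have equal length")

    def __len__(self) -> int:
        return len(self.samples)

    def replace(self, **kwargs) -> "SensorStream":
        """Copy of the stream with some fields replaced."""
        data = {
            "device_position": self.device_position,
            "sensor_kind": self.sensor_kind,
            "rate_hz": self.rate_hz,
            "samples": self.samples,
            "labels": self.labels,
            "subject_id": self.subject_id,
        }
        data.update(kwargs)
        return SensorStream(**data)


@dataclass
class Recording:
    """A set of simultaneously sampled streams from one subject/session."""

    streams: list[SensorStream]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.streams:
            n = len(self.streams[0])
            rate = self.streams[0].rate_hz
            subject = self.streams[0].subject_id
            for s in self.streams:
                if len(s) != n or s.rate_hz != rate:
                    raise ValueError(
                        "all streams in a recording must share length and rate"
                    )
                if s.subject_id != subject:
                    raise ValueError("all streams must share subject_id")

    @property
    def subject_id(self) -> str:
        return self.streams[0].subject_id

    @property
    def rate_hz(self) -> float:
        return self.streams[0].rate_hz

    def get_stream(self, device_position: str, sensor_kind: str) -> SensorStream:
        for s in self.streams:
            if s.device_position == device_position and s.sensor_kind == sensor_kind:
                return s
        raise KeyError(f"no stream {device_position}/{sensor_kind}")


@dataclass
class FeatureRecord:
    """Concatenated per-window feature vector with its label and provenance."""

    vector: np.ndarray
    label: str
    subject_id: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.ndim != 1:
            raise ValueError("vector must be one-dimensional")

    @property
    def dim(self) -> int:
        return len(self.vector)


class RawFormatError(ValueError):
    """A raw sensor log could not be parsed."""


def _parse_wisdm(path: Path) -> list[Recording]:
    samples: list[tuple[float, float, float]] = []
    labels: list[str] = []
    subjects: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            # one physical line may hold several ';'-terminated records
            for piece in raw.strip().split(";"):
                piece = piece.strip().strip(",")
                if not piece:
                    continue
                fields = piece.split(",")
                if len(fields) != 6:
                    raise RawFormatError(
                        f"{path}:{lineno}: expected 6 fields "
                        f"(user,activity,timestamp,x,y,z), got {len(fields)}"
                    )
                user, activity, _ts, sx, sy, sz = fields
                if activity not in WISDM_ACTIVITIES:
                    raise RawFormatError(
                        f"{path}:{lineno}: unknown activity {activity!r}; "
                        f"allowed: {sorted(WISDM_ACTIVITIES)}"
                    )
                try:
                    xyz = (float(sx), float(sy), float(sz))
                except ValueError as exc:
                    raise RawFormatError(
                        f"{path}:{lineno}: bad numeric field: {exc}"
                    ) from None
                samples.append(xyz)
                labels.append(activity)
                subjects.append(user)
    if not samples:
        raise RawFormatError(f"{path}: empty file")

    recordings: list[Recording] = []
    subjects_arr = np.asarray(subjects, dtype=object)
    # a new recording starts whenever the subject id changes
    breaks = [0] + [
        i for i in range(1, len(subjects_arr)) if subjects_arr[i] != subjects_arr[i - 1]
    ] + [len(subjects_arr)]
    for a, b in zip(breaks[:-1], breaks[1:]):
        stream = SensorStream(
            device_position="pocket",
            sensor_kind="accelerometer",
            rate_hz=20.0,
            samples=np.asarray(samples[a:b], dtype=float),
            labels=np.asarray(labels[a:b], dtype=object),
            subject_id=str(subjects_arr[a]),
        )
        recordings.append(Recording(streams=[stream], metadata={"dialect": "wisdm"}))
    return recordings


def _parse_shoaib(path: Path) -> list[Recording]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RawFormatError(f"{path}: empty file") from None
        expected = ["subject", "activity", "t_index"] + SHOAIB_STREAM_COLUMNS
        if header != expected:
            raise RawFormatError(
                f"{path}:1: unexpected header; expected columns {expected[:4]}..."
            )
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise RawFormatError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise RawFormatError(f"{path}: empty file")

    subjects = np.asarray([r[0] for r in rows], dtype=object)
    labels = np.asarray([r[1] for r in rows], dtype=object)
    try:
        values = np.asarray([[float(v) for v in r[3:]] for r in rows], dtype=float)
    except ValueError as exc:
        raise RawFormatError(f"{path}: bad numeric field: {exc}") from None

    recordings: list[Recording] = []
    breaks = [0] + [
        i for i in range(1, len(subjects)) if subjects[i] != subjects[i - 1]
    ] + [len(subjects)]
    for a, b in zip(breaks[:-1], breaks[1:]):
        streams = []
        for d_i, device in enumerate(("pocket", "wrist")):
            for s_i, sensor in enumerate(("accelerometer", "gyroscope")):
                cols = slice((d_i * 2 + s_i) * 3, (d_i * 2 + s_i) * 3 + 3)
                streams.append(
                    SensorStream(
                        device_position=device,
                        sensor_kind=sensor,
                        rate_hz=50.0,
                        samples=values[a:b, cols],
                        labels=labels[a:b],
                        subject_id=str(subjects[a]),
                    )
                )
        recordings.append(Recording(streams=streams, metadata={"dialect": "shoaib"}))
    return recordings


def read_raw_recording(path: str | Path, dialect: str) -> list[Recording]:
    """Read a raw sensor log into one Recording per contiguous subject block.

    Parameters
    ----------
    path : path to a delimited text file.
    dialect : {"shoaib", "wisdm"}
        ``shoaib``: canonical two-device wide CSV, 4 streams at 50 Hz.
        ``wisdm``: WISDM v1 raw grammar, 1 accelerometer stream at 20 Hz.

    Activity label changes do *not* split recordings; only subject changes do
    (the collection protocol records contiguous per-activity blocks).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wisdm":
        return _parse_wisdm(path)
    if dialect == "shoaib":
        return _parse_shoaib(path)
    raise ValueError(f"unknown dialect {dialect!r}; supported: shoaib, wisdm")


def write_raw_recording(recordings: Sequence[Recording], path: str | Path,
                        dialect: str) -> None:
    """Serialize recordings in one of the supported raw dialects."""
    path = Path(path)
    if dialect == "shoaib":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject", "activity", "t_index"] + SHOAIB_STREAM_COLUMNS)
            for rec in recordings:
                streams = [
                    rec.get_stream(device, sensor)
                    for device in ("pocket", "wrist")
                    for sensor in ("accelerometer", "gyroscope")
                ]
                n = len(streams[0])
                wide = np.hstack([s.samples for s in streams])
                labels = streams[0].labels
                for i in range(n):
                    writer.writerow(
                        [rec.subject_id, labels[i], i]
                        + [repr(float(v)) for v in wide[i]]
                    )
    elif dialect == "wisdm":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in recordings:
                stream = rec.get_stream("pocket", "accelerometer")
                # timestamps in ns at the nominal rate, WISDM-style
                step_ns = int(round(1e9 / stream.rate_hz))
                for i, (xyz, label) in enumerate(zip(stream.samples, stream.labels)):
                    fh.write(
                        f"{rec.subject_id},{label},{i * step_ns},"
                        f"{float(xyz[0])!r},{float(xyz[1])!r},{float(xyz[2])!r};\n"
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_feature_table(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write feature records as CSV: label, subject, then feature columns.

    All records must share one dimension; numbers are written with repr
    precision so a read round-trip is lossless.
    """
    records = list(records)
    path = Path(path)
    if records:
        dims = {r.dim for r in records}
        if len(dims) > 1:
            raise ValueError(f"mixed feature dimensions: {sorted(dims)}")
        dim = records[0].dim
        names = records[0].feature_names or [f"F{i + 1}" for i in range(dim)]
        if len(names) != dim:
            raise ValueError("feature_names length does not match dimension")
    else:
        names = []
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "subject"] + list(names))
        for rec in records:
            writer.writerow([rec.label, rec.subject_id] + [repr(float(v)) for v in rec.vector])


def read_feature_table(path: str | Path) -> list[FeatureRecord]:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"label": str, "subject": str})
    if "label" not in df.columns or "subject" not in df.columns:
        raise ValueError(f"{path}: not a feature table (missing label/subject)")
    feature_cols = [c for c in df.columns if c not in ("label", "subject")]
    values = df[feature_cols].to_numpy(dtype=float)
    return [
        FeatureRecord(
            vector=values[i],
            label=df["label"].iloc[i],
            subject_id=df["subject"].iloc[i],
            feature_names=list(feature_cols),
        )
        for i in range(len(df))
    ]
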