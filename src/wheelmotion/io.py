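"""Reading, validation and synchronization of raw IMU streams and annotations.

Two on-disk dialects are accepted for IMU data, one file per sensor:

* JSON: an array of records ``{"t_ms": int, "gyro": [x, y, z], "acc": [x, y, z]}``
  with gyro in degrees/second and acceleration in m/s^2;
* CSV: columns ``t_ms,gx,gy,gz,ax,ay,az`` with the same units.

Annotations are CSV with header
``start_s,end_s,label,participant_id,diagnosis,propulsion_mode``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SENSOR_ROLES = ("wheel", "frame")
LABELS = ("active", "passive")

__all__ = [
    "ImuStream",
    "WheelchairGeometry",
    "AnnotationTrack",
    "ImuParseError",
    "StreamValidationError",
    "read_imu",
    "write_imu",
    "read_annotations",
    "write_annotations",
    "synchronize",
]


class ImuParseError(ValueError):
    """Raised when an on-disk IMU or annotation file cannot be parsed."""


class StreamValidationError(ValueError):
    """Raised when parsed data violates a stream or track invariant."""


@dataclass
class ImuStream:
    """A timestamped 6-axis inertial stream from a single sensor.

    Attributes
    ----------
    sensor_role:
        ``"wheel"`` (hub-mounted, x-axis along the axle) or ``"frame"``
        (crossbar-mounted, z-axis vertical).
    timestamps:
        Seconds, strictly increasing, nominally sampled at ``sample_rate``.
    gyro:
        ``(n, 3)`` angular rates in degrees/second, sensor axes.
    accel:
        ``(n, 3)`` specific force in m/s^2, sensor axes.
    """

    sensor_role: str
    timestamps: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sensor_role not in SENSOR_ROLES:
            raise StreamValidationError(
                f"sensor_role must be one of {SENSOR_ROLES}, got {self.sensor_role!r}"
            )
        n = len(self.timestamps)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise StreamValidationError(
                f"gyro {self.gyro.shape} and accel {self.accel.shape} must both be ({n}, 3)"
            )
        if self.sample_rate <= 0:
            raise StreamValidationError("sample_rate must be positive")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise StreamValidationError(
                f"timestamps must be strictly increasing (violation at sample {bad + 1})"
            )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class WheelchairGeometry:
    """Wheel diameter and track width in meters, plus the sensed wheel side."""

    wheel_diameter: float = 0.6
    track_width: float = 0.56
    sensor_side: str = "right"

    def __post_init__(self) -> None:
        if self.wheel_diameter <= 0 or self.track_width <= 0:
            raise StreamValidationError("wheel_diameter and track_width must be positive")
        if self.sensor_side not in ("right", "left"):
            raise StreamValidationError("sensor_side must be 'right' or 'left'")

    @property
    def wheel_radius(self) -> float:
        return self.wheel_diameter / 2.0

    @property
    def side_sign(self) -> int:
        """+1 for a right-wheel sensor, -1 for left (flips roll/yaw conventions)."""
        return 1 if self.sensor_side == "right" else -1


@dataclass
class AnnotationTrack:
    """Manually timed active/passive intervals for one measurement.

    Intervals are ``(start_s, end_s, label)`` tuples, non-overlapping and kept
    sorted by start time.  Time not covered by any interval means "unknown".
    """

    intervals: list[tuple[float, float, str]]
    participant_id: str = ""
    diagnosis: str = ""
    propulsion_mode: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv[0])
        self.validate()

    def validate(self) -> None:
        for start, end, label in self.intervals:
            if not start < end:
                raise StreamValidationError(f"interval has start >= end: ({start}, {end})")
            if label not in LABELS:
                raise StreamValidationError(f"unknown annotation label {label!r}")
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise StreamValidationError(
                    f"overlapping annotation intervals at t={s1:.3f} s (previous ends {e0:.3f} s)"
                )


def _stream_from_columns(t_ms, gyro, accel, sensor_role, sample_rate):
    return ImuStream(
        sensor_role=sensor_role,
        timestamps=np.asarray(t_ms, dtype=float) / 1000.0,
        gyro=gyro,
        accel=accel,
        sample_rate=sample_rate,
    )


def read_imu(path: str | Path, sensor_role: str, sample_rate: float = 50.0) -> ImuStream:
    """Read an IMU stream in the JSON or CSV dialect (chosen by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            records = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ImuParseError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(records, list):
            raise ImuParseError(f"{path}: expected a JSON array of records")
        t_ms, gyro, accel = [], [], []
        for i, rec in enumerate(records):
            try:
                t_ms.append(int(rec["t_ms"]))
                g, a = rec["gyro"], rec["acc"]
                if len(g) != 3 or len(a) != 3:
                    raise ValueError("gyro/acc must have 3 components")
                gyro.append([float(x) for x in g])
                accel.append([float(x) for x in a])
            except (KeyError, TypeError, ValueError) as exc:
                raise ImuParseError(f"{path}: malformed record {i}: {exc}") from exc
        gyro = np.asarray(gyro, dtype=float).reshape(-1, 3)
        accel = np.asarray(accel, dtype=float).reshape(-1, 3)
    elif path.suffix.lower() == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pandas raises several parse error types
            raise ImuParseError(f"{path}: {exc}") from exc
        required = ["t_ms", "gx", "gy", "gz", "ax", "ay", "az"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ImuParseError(f"{path}: missing columns {missing}")
        t_ms = df["t_ms"].to_numpy()
        gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
        accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    else:
        raise ImuParseError(f"{path}: unsupported suffix {path.suffix!r} (use .json or .csv)")
    return _stream_from_columns(t_ms, gyro, accel, sensor_role, sample_rate)


def write_imu(stream: ImuStream, path: str | Path) -> None:
    """Write a stream in the dialect implied by the file suffix."""
    path = Path(path)
    t_ms = np.round(stream.timestamps * 1000.0).astype(int)
    if path.suffix.lower() == ".json":
        records = [
            {
                "t_ms": int(t),
                "gyro": [round(float(v), 6) for v in g],
                "acc": [round(float(v), 6) for v in a],
            }
            for t, g, a in zip(t_ms, stream.gyro, stream.accel)
        ]
        path.write_text(json.dumps(records))
    elif path.suffix.lower() == ".csv":
        df = pd.DataFrame(
            {
                "t_ms": t_ms,
                "gx": stream.gyro[:, 0],
                "gy": stream.gyro[:, 1],
                "gz": stream.gyro[:, 2],
                "ax": stream.accel[:, 0],
                "ay": stream.accel[:, 1],
                "az": stream.accel[:, 2],
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ImuParseError(f"{path}: unsupported suffix {path.suffix!r}")


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation track from interval-dialect CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ImuParseError(f"{path}: {exc}") from exc
    required = ["start_s", "end_s", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ImuParseError(f"{path}: missing columns {missing}")
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples(index=False)
    ]
    first = df.iloc[0] if len(df) else {}

    def _opt(col: str) -> str:
        return str(first[col]) if col in df.columns and len(df) else ""

    return AnnotationTrack(
        intervals=intervals,
        participant_id=_opt("participant_id"),
        diagnosis=_opt("diagnosis"),
        propulsion_mode=_opt("propulsion_mode"),
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    rows = [
        {
            "start_s": round(s, 6),
            "end_s": round(e, 6),
            "label": lab,
            "participant_id": track.participant_id,
            "diagnosis": track.diagnosis,
            "propulsion_mode": track.propulsion_mode,
        }
        for s, e, lab in track.intervals
    ]
    pd.DataFrame(
        rows,
        columns=["start_s", "end_s", "label", "participant_id", "diagnosis", "propulsion_mode"],
    ).to_csv(path, index=False)


def _interp_stream(stream: ImuStream, grid: np.ndarray, role: str) -> ImuStream:
    gyro = np.column_stack(
        [np.interp(grid, stream.timestamps, stream.gyro[:, k]) for k in range(3)]
    )
    accel = np.column_stack(
        [np.interp(grid, stream.timestamps, stream.accel[:, k]) for k in range(3)]
    )
    return ImuStream(role, grid.copy(), gyro, accel, stream.sample_rate)


def synchronize(
    wheel: ImuStream, frame: ImuStream, min_overlap: float = 2.0
) -> tuple[ImuStream, ImuStream]:
    """Resample both streams onto the wheel sensor's clock over their overlap.

    Sensors are assumed hardware-synchronized (shared clock); this only trims
    to the common time span and linearly interpolates the frame stream onto
    the wheel sample grid, so the operation is idempotent.
    """
    t0 = max(wheel.timestamps[0], frame.timestamps[0])
    t1 = min(wheel.timestamps[-1], frame.timestamps[-1])
    if t1 - t0 < min_overlap:
        raise StreamValidationError(
            f"streams overlap by {max(t1 - t0, 0):.3f} s; at least {min_overlap} s required"
        )
    mask = (wheel.timestamps >= t0) & (wheel.timestamps <= t1)
    grid = wheel.timestamps[mask]
    wheel_out = ImuStream(
        wheel.sensor_role, grid.copy(), wheel.gyro[mask], wheel.accel[mask], wheel.sample_rate
    )
    frame_out = _interp_stream(frame, grid, frame.sensor_role)
    return wheel_out, frame_out
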