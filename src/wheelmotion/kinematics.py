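"""Wheelchair kinematics from wheel- and frame-mounted inertial sensors.

Reference frames (right-wheel mounting, the default):

* wheel sensor: x along the axle pointing away from the chair; y and z spin
  with the wheel in the wheel plane, z up when the wheel angle is zero;
* frame sensor: x lateral (right), y forward, z vertical up;
* chair: positive yaw is a counter-clockwise (left) turn seen from above;
  positive roll is forward wheel spin, so forward speed is positive.

Two configurations are supported.  With both sensors (S2, the "full" setup)
yaw comes directly from the frame gyroscope.  With the wheel sensor alone
(S1) the spinning sensor's gyro signal is split into wheel roll, chair pitch
and chair yaw by tracking the wheel angle with a complementary attitude
filter (gyro integration corrected toward the gravity direction measured by
the accelerometer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import ImuStream, WheelchairGeometry, StreamValidationError

logger = logging.getLogger(__name__)

GRAVITY = 9.80665  # m/s^2
DEFAULT_MOTION_THRESHOLD = 5.0  # deg/s, "no motion" gyro magnitude
STATIONARY_MIN_RUN_S = 0.5  # a rest must persist this long to count
FREEFALL_ACCEL = 2.0  # m/s^2; below this the attitude filter trusts gyro only
COMPLEMENTARY_GAIN = 0.02  # per-sample accel weight at 50 Hz (~1 s time constant)
DIFF_CUTOFF_HZ = 6.0  # zero-phase low-pass before differentiation

__all__ = [
    "KinematicSeries",
    "Path2D",
    "stationary_mask",
    "correct_gyro_offset",
    "wheel_speed",
    "chair_speed",
    "yaw_rate_from_frame",
    "decompose_wheel_gyro",
    "differentiate",
    "reconstruct_path",
    "compute_kinematics",
]


@dataclass
class KinematicSeries:
    """Chair-level kinematics on a uniform clock.

    ``forward_speed`` is signed (reverse driving is negative); segmentation
    takes the magnitude.  Angular rates are in degrees/second, accelerations
    in degrees/second^2, ``wheel_angle`` is the unwrapped wheel rotation in
    degrees.  ``source`` is ``"S1"`` (wheel only) or ``"S2"`` (wheel+frame).
    """

    timestamps: np.ndarray
    forward_speed: np.ndarray
    forward_accel: np.ndarray
    yaw_rate: np.ndarray
    roll_rate: np.ndarray
    pitch_rate: np.ndarray
    yaw_accel: np.ndarray
    roll_accel: np.ndarray
    pitch_accel: np.ndarray
    wheel_angle: np.ndarray
    source: str
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in (
            "forward_speed",
            "forward_accel",
            "yaw_rate",
            "roll_rate",
            "pitch_rate",
            "yaw_accel",
            "roll_accel",
            "pitch_accel",
            "wheel_angle",
        ):
            if len(getattr(self, name)) != n:
                raise StreamValidationError(f"{name} length differs from timestamps")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Path2D:
    """Planar dead-reckoned path: positions in meters, heading in degrees."""

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    total_distance: float


def stationary_mask(
    stream: ImuStream,
    threshold: float = DEFAULT_MOTION_THRESHOLD,
    min_run_s: float = STATIONARY_MIN_RUN_S,
) -> np.ndarray:
    """Boolean mask of no-motion periods from a stream's gyro magnitude.

    A sample is stationary when the gyro magnitude stays below ``threshold``
    (deg/s) over the whole window of ``min_run_s`` seconds centered on it
    (morphological erosion of the below-threshold mask).  Reading "periods
    of no motion" strictly this way keeps the onset and tail of speed
    ramps — where the gyro passes through low rates while the chair is
    already moving — out of the bias estimate.  The wheel sensor is the
    preferred motion witness (any translation spins it fast) and its mask
    can be reused to correct the frame stream, whose own gyro stays small
    during gentle turning.
    """
    below = np.linalg.norm(stream.gyro, axis=1) < threshold
    guard = int(round(min_run_s * stream.sample_rate / 2.0))
    if guard < 1:
        return below
    window = 2 * guard + 1
    ok = np.convolve(below.astype(np.int32), np.ones(window, dtype=np.int32), "same")
    return ok == window


def correct_gyro_offset(
    stream: ImuStream,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
    mask: np.ndarray | None = None,
) -> ImuStream:
    """Subtract the per-axis gyro bias estimated over stationary periods.

    The bias is the mean gyro value over samples whose gyro magnitude stays
    below ``motion_threshold`` (deg/s) for at least half a second; a
    precomputed stationarity ``mask`` (e.g. from the wheel sensor on the
    same clock) may be supplied instead.  If the stream contains no such
    period it is returned unchanged with a warning.  Accelerometer data are
    untouched.  Idempotent up to the residual noise mean (a second pass
    re-estimates a bias that is already ~0).
    """
    if mask is None:
        mask = stationary_mask(stream, motion_threshold)
    if not mask.any():
        logger.warning(
            "%s stream: no stationary period below %.1f deg/s; gyro offset not corrected",
            stream.sensor_role,
            motion_threshold,
        )
        return stream
    bias = stream.gyro[mask].mean(axis=0)
    return ImuStream(
        stream.sensor_role,
        stream.timestamps.copy(),
        stream.gyro - bias,
        stream.accel.copy(),
        stream.sample_rate,
    )


def wheel_speed(wheel: ImuStream, geometry: WheelchairGeometry) -> np.ndarray:
    """Signed wheel-contact speed v = omega_roll * r in m/s.

    The roll-axis (axle) gyro component is the x channel; forward motion is
    positive for the configured mounting side.
    """
    omega = np.deg2rad(wheel.gyro[:, 0]) * geometry.side_sign
    return omega * geometry.wheel_radius


def chair_speed(
    v_wheel: np.ndarray, yaw_rate: np.ndarray, geometry: WheelchairGeometry
) -> np.ndarray:
    """Chair-center speed from one wheel's speed and the yaw rate.

    During a turn the sensed wheel travels faster or slower than the chair
    center by half the track width times the yaw rate; a right-wheel sensor
    is on the outside of a positive (leftward) turn.
    """
    v_wheel = np.asarray(v_wheel, dtype=float)
    yaw_rate = np.asarray(yaw_rate, dtype=float)
    if v_wheel.shape != yaw_rate.shape:
        raise StreamValidationError(
            f"v_wheel length {v_wheel.shape} != yaw_rate length {yaw_rate.shape}"
        )
    return v_wheel - geometry.side_sign * np.deg2rad(yaw_rate) * geometry.track_width / 2.0


def yaw_rate_from_frame(frame: ImuStream | None) -> np.ndarray:
    """Chair yaw rate (deg/s) from the frame sensor: its vertical-axis gyro."""
    if frame is None:
        raise StreamValidationError(
            "frame stream missing: use the wheel-only (S1) decomposition instead"
        )
    return frame.gyro[:, 2].copy()


def decompose_wheel_gyro(
    wheel: ImuStream,
    gain: float = COMPLEMENTARY_GAIN,
    side_sign: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split the spinning wheel sensor's gyro into roll, pitch and yaw rates.

    Returns ``(roll_rate, pitch_rate, yaw_rate, wheel_angle)`` in deg/s and
    degrees.  The wheel angle theta is tracked by a complementary filter:
    the gyro x channel is integrated and corrected each sample toward the
    gravity direction seen in the sensor y-z accelerometer plane with weight
    ``gain``.  Chair yaw and pitch are then the gyro y/z components rotated
    back through theta:

        yaw   =  g_y sin(theta) + g_z cos(theta)
        pitch = -g_y cos(theta) + g_z sin(theta)

    Samples with near-free-fall acceleration magnitude hold the gyro-only
    integration (gravity direction unobservable).
    """
    n = len(wheel)
    dt = 1.0 / wheel.sample_rate
    # theta integrates the RAW x gyro so it matches the accelerometer angle
    # for either mounting side; only the reported roll rate is side-signed.
    gx = wheel.gyro[:, 0]
    gy = wheel.gyro[:, 1]
    gz = wheel.gyro[:, 2]
    ay = wheel.accel[:, 1]
    az = wheel.accel[:, 2]
    acc_norm = np.linalg.norm(wheel.accel, axis=1)
    observable = acc_norm >= FREEFALL_ACCEL
    theta_acc = np.arctan2(ay, az)  # rad, wrapped

    theta = np.empty(n)
    th = theta_acc[0] if observable[0] else 0.0
    theta[0] = th
    held = 0
    for i in range(1, n):
        th = th + np.deg2rad(gx[i]) * dt
        if observable[i]:
            err = theta_acc[i] - th
            err = (err + np.pi) % (2.0 * np.pi) - np.pi  # wrap innovation
            th = th + gain * err
        else:
            held += 1
        theta[i] = th
    if held:
        logger.info("attitude filter held gyro-only integration for %d samples", held)

    sin_t, cos_t = np.sin(theta), np.cos(theta)
    yaw_rate = gy * sin_t + gz * cos_t
    pitch_rate = -gy * cos_t + gz * sin_t
    roll_rate = gx * side_sign
    return roll_rate, pitch_rate, yaw_rate, np.rad2deg(theta)


def differentiate(series: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Time derivative: zero-phase 6 Hz low-pass then central differences.

    The second-order Butterworth filter is applied forward-backward
    (zero phase); endpoints use one-sided differences.  Series shorter than
    the filter warm-up fall back to raw differences.
    """
    series = np.asarray(series, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(series) < 2:
        return np.zeros_like(series)
    dt = float(np.median(np.diff(timestamps)))
    fs = 1.0 / dt
    if len(series) >= 9 and DIFF_CUTOFF_HZ < fs / 2.0:
        b, a = signal.butter(2, DIFF_CUTOFF_HZ, fs=fs)
        smoothed = signal.filtfilt(b, a, series)
    else:
        if len(series) < 9:
            logger.debug("series of length %d below filter warm-up; raw differences", len(series))
        smoothed = series
    return np.gradient(smoothed, timestamps)


def reconstruct_path(kin: KinematicSeries) -> Path2D:
    """Dead-reckon the planar path from speed and yaw rate.

    Heading is the running integral of the yaw rate (trapezoidal, starting
    at zero); positions integrate v*cos(psi), v*sin(psi) with the trapezoid
    rule.  Total distance is the integral of |v|.
    """
    t = kin.timestamps
    v = kin.forward_speed
    psi_rad = np.deg2rad(_cumtrapz(kin.yaw_rate, t))
    dx = v * np.cos(psi_rad)
    dy = v * np.sin(psi_rad)
    x = _cumtrapz(dx, t)
    y = _cumtrapz(dy, t)
    distance = float(np.trapezoid(np.abs(v), t))
    return Path2D(x=x, y=y, heading=np.rad2deg(psi_rad), total_distance=distance)


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(y, dtype=float))
    out[1:] = np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)
    return out


def compute_kinematics(
    wheel: ImuStream,
    geometry: WheelchairGeometry,
    frame: ImuStream | None = None,
    variant: str = "S2",
    correct_offset: bool = True,
) -> KinematicSeries:
    """Full chain from raw stream(s) to a :class:`KinematicSeries`.

    ``variant="S2"`` requires the frame stream (yaw from its vertical gyro);
    ``variant="S1"`` uses the wheel sensor alone via the attitude filter.
    """
    if variant not in ("S1", "S2"):
        raise StreamValidationError(f"variant must be 'S1' or 'S2', got {variant!r}")
    if variant == "S2" and frame is None:
        raise StreamValidationError("variant S2 requires a frame stream")
    if variant == "S2" and len(frame) != len(wheel):
        raise StreamValidationError("S2 requires synchronized streams of equal length")
    if correct_offset:
        # the wheel sensor witnesses chair motion directly; its stationarity
        # mask also governs the frame sensor's bias estimate
        mask = stationary_mask(wheel)
        wheel = correct_gyro_offset(wheel, mask=mask)
        if variant == "S2":
            frame = correct_gyro_offset(frame, mask=mask)

    t = wheel.timestamps
    v_wheel = wheel_speed(wheel, geometry)
    if variant == "S2":
        yaw = yaw_rate_from_frame(frame)
        roll = wheel.gyro[:, 0] * geometry.side_sign
        pitch = frame.gyro[:, 0].copy()
        theta = _cumtrapz(roll, t)
    else:
        roll, pitch, yaw, theta = decompose_wheel_gyro(
            wheel, side_sign=geometry.side_sign
        )
    v = chair_speed(v_wheel, yaw, geometry)
    return KinematicSeries(
        timestamps=t,
        forward_speed=v,
        forward_accel=differentiate(v, t),
        yaw_rate=yaw,
        roll_rate=roll,
        pitch_rate=pitch,
        yaw_accel=differentiate(yaw, t),
        roll_accel=differentiate(roll, t),
        pitch_accel=differentiate(pitch, t),
        wheel_angle=theta,
        source=variant,
        sample_rate=wheel.sample_rate,
    )
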