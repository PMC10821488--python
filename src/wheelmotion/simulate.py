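"""Synthetic wheelchair trials: trajectories, IMU streams and annotations.

The generator emulates a semi-structured rehabilitation measurement: short
9 m test bouts (slow, normal speed, slalom, stop-and-go with two
near-standstills), driven both by the participant and by an attendant, plus
free movement around the center.  Active propulsion shows push-cadence
speed oscillation (~1 Hz) and yaw jitter; attendant pushing is faster,
smoother, with a mild walking sway.  Trajectories are planar and slip-free;
the IMU rendering is the exact inverse of the kinematics reconstruction
(wheel spin from forward speed, wheel-frame gravity rotation, centripetal
and tangential accelerations) plus white noise and a constant per-trial
gyro bias.

Default style parameters are fixed to the study regime they emulate: mean
self-propulsion speed ~0.56 m/s after stroke and ~0.68 m/s after
amputation, attendant pushing ~1.15 m/s, a ~55/45 active/passive segment
mix, about 950 segments per 24-participant cohort, mostly shorter than
20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import AnnotationTrack, ImuStream, WheelchairGeometry
from .kinematics import GRAVITY

SAMPLE_RATE = 50.0

__all__ = [
    "PropulsionStyle",
    "Bout",
    "ProtocolScript",
    "NoiseModel",
    "TrajectoryTruth",
    "SimulatedTrial",
    "ACTIVE_DEFAULTS",
    "PASSIVE_DEFAULTS",
    "simulate_trajectory",
    "render_imu",
    "simulate_trial",
    "build_participant_script",
    "generate_cohort",
]


@dataclass(frozen=True)
class PropulsionStyle:
    """Numeric description of how the chair is being moved in one bout.

    All behavior derives from the numeric fields so that active and passive
    styles can be made literally identical (for null experiments); ``kind``
    is descriptive only.
    """

    kind: str = "active_bimanual"
    mean_speed: float = 0.6  # m/s
    push_frequency: float = 1.0  # Hz, speed-oscillation cadence
    speed_oscillation_fraction: float = 0.25  # peak fractional speed modulation
    yaw_jitter_sd: float = 6.0  # deg/s, low-frequency steering noise
    sway_amp: float = 0.0  # deg/s, sinusoidal sway (attendant gait)
    sway_hz: float = 0.3
    wobble_amp: float = 0.0  # deg/s push-locked yaw wobble (one hand + one foot)
    backward: bool = False

    def __post_init__(self) -> None:
        if self.push_frequency <= 0:
            raise ValueError("push_frequency must be positive")
        if not 0 <= self.speed_oscillation_fraction < 1:
            raise ValueError("speed_oscillation_fraction must be in [0, 1)")


ACTIVE_DEFAULTS = PropulsionStyle(
    kind="active_bimanual",
    mean_speed=0.6,
    push_frequency=1.0,
    speed_oscillation_fraction=0.25,
    yaw_jitter_sd=6.0,
)
PASSIVE_DEFAULTS = PropulsionStyle(
    kind="passive_attendant",
    mean_speed=1.15,
    push_frequency=1.0,
    speed_oscillation_fraction=0.05,
    yaw_jitter_sd=2.5,
    sway_amp=3.0,
    sway_hz=0.3,
)

BOUT_KINDS = ("slow_9m", "normal_9m", "slalom_9m", "stop_go_9m", "free_roam")


@dataclass(frozen=True)
class Bout:
    """One scripted movement bout preceded by a standstill rest."""

    kind: str
    style: PropulsionStyle
    label: str  # "active" | "passive" ground truth
    distance_m: float | None = 9.0
    duration_s: float | None = None
    rest_before_s: float = 2.0
    turn_rate: float = 0.0  # deg/s constant heading drift (free roam)

    def __post_init__(self) -> None:
        if self.kind not in BOUT_KINDS:
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.distance_m is None and self.duration_s is None:
            raise ValueError("bout needs a distance or a duration")
        if (self.distance_m or 1) <= 0 or (self.duration_s or 1) <= 0:
            raise ValueError("bout distance/duration must be positive")


@dataclass
class ProtocolScript:
    bouts: list[Bout]
    tail_rest_s: float = 3.0


@dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfection model (typical MEMS figures)."""

    gyro_sd: float = 0.5  # deg/s white noise
    accel_sd: float = 0.05  # m/s^2 white noise
    gyro_bias: float = 2.0  # deg/s, uniform +/- per axis per trial

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass
class TrajectoryTruth:
    """Ground-truth chair kinematics: signed center speed and yaw rate."""

    timestamps: np.ndarray
    speed: np.ndarray  # m/s, chair center, signed
    yaw_rate: np.ndarray  # deg/s, positive = left turn
    intervals: list[tuple[float, float, str]]
    sample_rate: float = SAMPLE_RATE

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SimulatedTrial:
    participant_id: str
    diagnosis: str
    propulsion_mode: str
    truth: TrajectoryTruth
    wheel: ImuStream
    frame: ImuStream
    annotations: AnnotationTrack
    seed: int


def _smooth_noise(n: int, sd: float, rng: np.random.Generator, cutoff_hz: float = 1.5) -> np.ndarray:
    """Band-limited noise with the requested standard deviation."""
    if sd <= 0 or n < 12:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz, fs=SAMPLE_RATE)
    x = signal.filtfilt(b, a, white)
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _bout_speed(style: PropulsionStyle, n: int, rng: np.random.Generator) -> np.ndarray:
    """Trapezoidal base profile with push-cadence oscillation."""
    dt = 1.0 / SAMPLE_RATE
    t = np.arange(n) * dt
    duration = n * dt
    ramp = min(1.0, duration / 4.0)
    base = np.minimum.reduce(
        [np.full(n, 1.0), t / ramp, np.maximum((duration - t) / ramp, 0.0)]
    )
    v = style.mean_speed * base
    osc = style.speed_oscillation_fraction
    if osc > 0:
        phase = rng.uniform(0, 2 * np.pi)
        cycles = np.floor(style.push_frequency * t + phase / (2 * np.pi)).astype(int)
        n_cycles = cycles.max() + 1 if n else 0
        amp_jitter = 1.0 + 0.25 * rng.standard_normal(max(n_cycles, 1))
        amp = osc * np.clip(amp_jitter, 0.3, 1.8)[cycles]
        mod = 1.0 + amp * np.sin(2 * np.pi * style.push_frequency * t + phase)
        v = v * np.clip(mod, 0.15, None)
    v = v * (1.0 + _smooth_noise(n, 0.02, rng, cutoff_hz=0.5))
    return -v if style.backward else v


def _bout_yaw(
    bout: Bout, style: PropulsionStyle, n: int, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / SAMPLE_RATE
    omega = _smooth_noise(n, style.yaw_jitter_sd, rng)
    if style.sway_amp > 0:
        omega = omega + style.sway_amp * np.sin(
            2 * np.pi * style.sway_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if style.wobble_amp > 0:
        omega = omega + style.wobble_amp * np.sin(
            2 * np.pi * style.push_frequency * t + rng.uniform(0, 2 * np.pi)
        )
    if bout.kind == "slalom_9m":
        omega = omega + 30.0 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(-0.3, 0.3))
    if bout.turn_rate:
        omega = omega + bout.turn_rate
    # taper turning at the standstill boundaries
    edge = min(int(0.5 * SAMPLE_RATE), max(n // 8, 1))
    taper = np.ones(n)
    taper[:edge] = np.linspace(0.0, 1.0, edge)
    taper[-edge:] = np.linspace(1.0, 0.0, edge)
    return omega * taper


def _stop_go_notches(v: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Two near-standstill dips splitting the bout into three runs."""
    t = np.arange(n) / SAMPLE_RATE
    duration = n / SAMPLE_RATE
    out = v.copy()
    for frac in (1.0 / 3.0, 2.0 / 3.0):
        tc = duration * frac + rng.uniform(-0.3, 0.3)
        out = out * (1.0 - 0.98 * np.exp(-((t - tc) ** 2) / (2 * 0.35**2)))
    return out


def simulate_trajectory(
    script: ProtocolScript, seed: int = 0, sample_rate: float = SAMPLE_RATE
) -> TrajectoryTruth:
    """Render a script into ground-truth speed/yaw series plus annotations."""
    if sample_rate != SAMPLE_RATE:
        raise ValueError("the generator is defined at 50 Hz")
    rng = np.random.default_rng(seed)
    v_parts: list[np.ndarray] = []
    w_parts: list[np.ndarray] = []
    intervals: list[tuple[float, float, str]] = []
    cursor = 0  # samples emitted so far
    for bout in script.bouts:
        n_rest = int(round(bout.rest_before_s * SAMPLE_RATE))
        v_parts.append(np.zeros(n_rest))
        w_parts.append(np.zeros(n_rest))
        cursor += n_rest
        style = bout.style
        if bout.duration_s is not None:
            duration = bout.duration_s
        else:
            duration = bout.distance_m / abs(style.mean_speed)
        n = max(int(round(duration * SAMPLE_RATE)), 2)
        v = _bout_speed(style, n, rng)
        if bout.kind == "stop_go_9m":
            v = _stop_go_notches(v, n, rng)
        w = _bout_yaw(bout, style, n, rng)
        v_parts.append(v)
        w_parts.append(w)
        intervals.append((cursor / SAMPLE_RATE, (cursor + n - 1) / SAMPLE_RATE, bout.label))
        cursor += n
    n_tail = int(round(script.tail_rest_s * SAMPLE_RATE))
    v_parts.append(np.zeros(n_tail))
    w_parts.append(np.zeros(n_tail))
    cursor += n_tail
    t = np.arange(cursor) / SAMPLE_RATE
    return TrajectoryTruth(
        timestamps=t,
        speed=np.concatenate(v_parts),
        yaw_rate=np.concatenate(w_parts),
        intervals=intervals,
    )


def render_imu(
    truth: TrajectoryTruth,
    geometry: WheelchairGeometry = WheelchairGeometry(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[ImuStream, ImuStream]:
    """Render the trajectory into wheel- and frame-sensor streams.

    The wheel sensor spins with the wheel: its x gyro is the wheel spin
    rate, its y/z gyro carry the chair yaw rate rotated through the wheel
    angle, and its accelerometer sees gravity rotating in the y-z plane
    plus the tangential and centripetal accelerations of the hub.  The
    frame sensor reads the yaw rate on its vertical z axis directly.
    White noise and a constant per-trial gyro bias are then added.
    """
    rng = np.random.default_rng(seed)
    t = truth.timestamps
    n = len(t)
    v = truth.speed
    omega_rad = np.deg2rad(truth.yaw_rate)
    side = geometry.side_sign
    r = geometry.wheel_radius

    v_wheel = v + side * omega_rad * geometry.track_width / 2.0
    gx_raw_rad = v_wheel / r  # raw sensor x gyro before side signing
    wheel_gx = np.rad2deg(gx_raw_rad) * side
    theta = np.zeros(n)
    theta[1:] = np.cumsum(np.diff(t) * (gx_raw_rad[1:] + gx_raw_rad[:-1]) / 2.0)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    wheel_gy = truth.yaw_rate * sin_t
    wheel_gz = truth.yaw_rate * cos_t

    dvw = np.gradient(v_wheel, t)
    dv = np.gradient(v, t)
    lateral = -v * omega_rad  # centripetal, toward the turn center
    wheel_ax = lateral.copy()
    wheel_ay = dvw * cos_t + GRAVITY * sin_t
    wheel_az = -dvw * sin_t + GRAVITY * cos_t

    frame_g = np.column_stack([np.zeros(n), np.zeros(n), truth.yaw_rate])
    frame_a = np.column_stack([lateral, dv, np.full(n, GRAVITY)])

    def _noisy(gyro: np.ndarray, accel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bias = rng.uniform(-noise.gyro_bias, noise.gyro_bias, size=3)
        g = gyro + bias + rng.normal(0.0, noise.gyro_sd, size=gyro.shape)
        a = accel + rng.normal(0.0, noise.accel_sd, size=accel.shape)
        return g, a

    wheel_gyro = np.column_stack([wheel_gx, wheel_gy, wheel_gz])
    wheel_accel = np.column_stack([wheel_ax, wheel_ay, wheel_az])
    wheel_gyro, wheel_accel = _noisy(wheel_gyro, wheel_accel)
    frame_g, frame_a = _noisy(frame_g, frame_a)

    wheel = ImuStream("wheel", t.copy(), wheel_gyro, wheel_accel, truth.sample_rate)
    frame = ImuStream("frame", t.copy(), frame_g, frame_a, truth.sample_rate)
    return wheel, frame


def simulate_trial(
    script: ProtocolScript,
    geometry: WheelchairGeometry = WheelchairGeometry(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    participant_id: str = "P00",
    diagnosis: str = "stroke",
    propulsion_mode: str = "bimanual",
) -> SimulatedTrial:
    ss = np.random.SeedSequence(seed)
    traj_seed, imu_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    truth = simulate_trajectory(script, seed=traj_seed)
    wheel, frame = render_imu(truth, geometry, noise, seed=imu_seed)
    track = AnnotationTrack(
        intervals=list(truth.intervals),
        participant_id=participant_id,
        diagnosis=diagnosis,
        propulsion_mode=propulsion_mode,
    )
    return SimulatedTrial(
        participant_id=participant_id,
        diagnosis=diagnosis,
        propulsion_mode=propulsion_mode,
        truth=truth,
        wheel=wheel,
        frame=frame,
        annotations=track,
        seed=seed,
    )


def _participant_styles(
    diagnosis: str, rng: np.random.Generator, distinguishable: bool
) -> tuple[PropulsionStyle, PropulsionStyle, str]:
    """Draw the active and passive styles for one participant."""
    if diagnosis == "stroke":
        mean_speed = float(np.clip(rng.normal(0.56, 0.06), 0.35, 1.0))
        if rng.random() < 4.0 / 11.0:
            mode = "one_hand_one_foot"
            active = replace(
                ACTIVE_DEFAULTS,
                kind="active_one_hand_one_foot",
                mean_speed=mean_speed,
                push_frequency=float(rng.normal(0.9, 0.1)),
                speed_oscillation_fraction=float(np.clip(rng.normal(0.22, 0.05), 0.10, 0.40)),
                yaw_jitter_sd=float(np.clip(rng.normal(8.0, 1.5), 2.0, 14.0)),
                wobble_amp=8.0,
            )
        else:
            mode = "bimanual"
            active = replace(
                ACTIVE_DEFAULTS,
                mean_speed=mean_speed,
                push_frequency=float(rng.normal(1.0, 0.1)),
                speed_oscillation_fraction=float(np.clip(rng.normal(0.25, 0.05), 0.12, 0.40)),
                yaw_jitter_sd=float(np.clip(rng.normal(6.0, 1.5), 2.0, 12.0)),
            )
    else:  # amputation
        mean_speed = float(np.clip(rng.normal(0.68, 0.06), 0.35, 1.1))
        if rng.random() < 1.0 / 13.0:
            mode = "backward_foot"
            active = replace(
                ACTIVE_DEFAULTS,
                kind="active_backward_foot",
                mean_speed=mean_speed,
                push_frequency=float(rng.normal(0.8, 0.08)),
                speed_oscillation_fraction=float(np.clip(rng.normal(0.20, 0.04), 0.10, 0.35)),
                yaw_jitter_sd=float(np.clip(rng.normal(7.0, 1.5), 2.0, 12.0)),
                backward=True,
            )
        else:
            mode = "bimanual"
            active = replace(
                ACTIVE_DEFAULTS,
                mean_speed=mean_speed,
                push_frequency=float(rng.normal(1.0, 0.1)),
                speed_oscillation_fraction=float(np.clip(rng.normal(0.25, 0.05), 0.12, 0.40)),
                yaw_jitter_sd=float(np.clip(rng.normal(6.0, 1.5), 2.0, 12.0)),
            )
    passive = replace(
        PASSIVE_DEFAULTS,
        mean_speed=float(np.clip(rng.normal(1.15, 0.2), 0.6, 1.6)),
        speed_oscillation_fraction=float(np.clip(rng.normal(0.05, 0.02), 0.01, 0.12)),
        yaw_jitter_sd=float(np.clip(rng.normal(2.5, 0.8), 0.5, 5.0)),
    )
    if not distinguishable:
        # null experiment: attendant bouts are statistically identical to
        # the participant's own, so only the labels differ
        passive = replace(active, kind="passive_attendant")
    return active, passive, mode


def build_participant_script(
    active: PropulsionStyle,
    passive: PropulsionStyle,
    rng: np.random.Generator,
) -> ProtocolScript:
    """Protocol (self + attendant) followed by free movement around the center."""
    bouts: list[Bout] = []

    def protocol(style: PropulsionStyle, label: str) -> None:
        slow = replace(style, mean_speed=0.6 * style.mean_speed)
        for kind, st in (
            ("slow_9m", slow),
            ("normal_9m", style),
            ("slalom_9m", style),
            ("stop_go_9m", style),
        ):
            bouts.append(
                Bout(
                    kind=kind,
                    style=st,
                    label=label,
                    distance_m=9.0,
                    rest_before_s=float(rng.uniform(1.5, 3.0)),
                )
            )

    protocol(active, "active")
    protocol(passive, "passive")

    n_active = max(4, int(round(rng.normal(16, 2))))
    n_passive = max(4, int(round(rng.normal(12, 2))))
    free = ["active"] * n_active + ["passive"] * n_passive
    rng.shuffle(free)
    for label in free:
        style = active if label == "active" else passive
        style = replace(style, mean_speed=style.mean_speed * float(rng.uniform(0.75, 1.25)))
        bouts.append(
            Bout(
                kind="free_roam",
                style=style,
                label=label,
                distance_m=None,
                duration_s=float(rng.uniform(4.0, 16.0)),
                rest_before_s=float(rng.uniform(1.5, 3.0)),
                turn_rate=float(rng.uniform(-12.0, 12.0)),
            )
        )
    return ProtocolScript(bouts=bouts)


def generate_cohort(
    n_participants: int = 24,
    seed: int = 0,
    geometry: WheelchairGeometry = WheelchairGeometry(),
    noise: NoiseModel = NoiseModel(),
    distinguishable: bool = True,
) -> list[SimulatedTrial]:
    """Simulate a cohort: ~11/13 stroke/amputation split, one trial each.

    With ``distinguishable=False`` every attendant bout reuses the
    participant's own style, removing all class signal (labels become
    unlearnable); used to verify that classifier performance is
    signal-driven.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    ss = np.random.SeedSequence(seed)
    n_stroke = int(round(n_participants * 11.0 / 24.0))
    trials = []
    for i, child in enumerate(ss.spawn(n_participants)):
        states = child.generate_state(2) % (2**31)
        rng = np.random.default_rng(int(states[0]))
        diagnosis = "stroke" if i < n_stroke else "amputation"
        active, passive, mode = _participant_styles(diagnosis, rng, distinguishable)
        script = build_participant_script(active, passive, rng)
        trials.append(
            simulate_trial(
                script,
                geometry=geometry,
                noise=noise,
                seed=int(states[1]),
                participant_id=f"P{i:02d}",
                diagnosis=diagnosis,
                propulsion_mode=mode,
            )
        )
    return trials
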