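"""Per-segment aggregate features and multicollinearity pruning.

Each segment is summarized by 56 named predictors, for either sensor
configuration:

* derived block (8 series x 4 aggregates = 32): the FFT amplitude spectrum
  of the chair's linear speed, the linear acceleration, and the angular
  velocities and accelerations about the roll, pitch and yaw axes;
* raw block (6 series x 4 aggregates = 24): the three raw gyro channels of
  the configuration's own sensor (wheel for S1, frame for S2) and their
  time derivatives.

The four aggregates, in fixed order, are median, standard deviation
(population, n denominator), moment skewness g1 and excess kurtosis g2; a
constant series aggregates to (value, 0, 0, 0).  Column naming is
``<series>_<aggregate>``, and the canonical column order (derived block then
raw block, aggregates innermost) determines the scan order of the greedy
|r| > 0.7 correlation pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ImuStream
from .kinematics import KinematicSeries, differentiate
from .segmentation import Segment

AGGREGATES = ("median", "sd", "skew", "kurt")
DERIVED_SERIES = (
    "speed_fft",
    "linear_accel",
    "roll_rate",
    "pitch_rate",
    "yaw_rate",
    "roll_accel",
    "pitch_accel",
    "yaw_accel",
)
RAW_SERIES = ("gyro_x", "gyro_y", "gyro_z", "gyro_x_deriv", "gyro_y_deriv", "gyro_z_deriv")

CANONICAL_COLUMNS = tuple(
    f"{series}_{agg}" for series in DERIVED_SERIES + RAW_SERIES for agg in AGGREGATES
)
META_COLUMNS = ("y", "participant_id", "diagnosis")

__all__ = [
    "AGGREGATES",
    "DERIVED_SERIES",
    "RAW_SERIES",
    "CANONICAL_COLUMNS",
    "FeatureMatrix",
    "aggregate",
    "fft_amplitudes",
    "build_feature_matrix",
    "prune_correlated",
]


@dataclass
class FeatureMatrix:
    """Predictor table: one row per labeled segment plus target and strata.

    ``data`` holds the 56 predictor columns in canonical order, the binary
    target ``y`` (1 = active, 0 = passive) and the stratification columns
    ``participant_id`` and ``diagnosis``.
    """

    data: pd.DataFrame
    variant: str

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS + META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")
        if self.data[list(CANONICAL_COLUMNS)].isna().any().any():
            raise ValueError("feature matrix contains missing predictor values")
        if not set(self.data["y"].unique()) <= {0, 1}:
            raise ValueError("target y must be binary 0/1")

    @property
    def predictors(self) -> pd.DataFrame:
        return self.data[list(CANONICAL_COLUMNS)]

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def aggregate(series: np.ndarray) -> tuple[float, float, float, float]:
    """(median, population SD, moment skewness g1, excess kurtosis g2).

    A constant series returns (value, 0, 0, 0): the higher moments are 0/0
    and resolved to zero so degenerate segments stay usable.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty series")
    med = float(np.median(x))
    sd = float(np.std(x))  # ddof=0
    if sd == 0.0:
        return med, 0.0, 0.0, 0.0
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return med, sd, skew, kurt


def fft_amplitudes(v: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided discrete-Fourier amplitude spectrum of a speed segment.

    The mean is removed, amplitudes are 2|c_k|/N for the positive-frequency
    bins (DC excluded), so a sine of amplitude A aligned with bin k reports
    amplitude A at its frequency.  Returns ``(frequencies_hz, amplitudes)``.
    """
    x = np.asarray(v, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("segment too short for a spectrum")
    coeffs = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    amps = 2.0 * np.abs(coeffs) / n
    return freqs[1:], amps[1:]


def _segment_series(kin: KinematicSeries, raw: ImuStream) -> dict[str, np.ndarray]:
    t = kin.timestamps
    raw_gyro = raw.gyro
    return {
        "linear_accel": kin.forward_accel,
        "roll_rate": kin.roll_rate,
        "pitch_rate": kin.pitch_rate,
        "yaw_rate": kin.yaw_rate,
        "roll_accel": kin.roll_accel,
        "pitch_accel": kin.pitch_accel,
        "yaw_accel": kin.yaw_accel,
        "gyro_x": raw_gyro[:, 0],
        "gyro_y": raw_gyro[:, 1],
        "gyro_z": raw_gyro[:, 2],
        "gyro_x_deriv": differentiate(raw_gyro[:, 0], t),
        "gyro_y_deriv": differentiate(raw_gyro[:, 1], t),
        "gyro_z_deriv": differentiate(raw_gyro[:, 2], t),
    }


def build_feature_matrix(
    segments: list[Segment],
    kin: KinematicSeries,
    raw: ImuStream,
    variant: str,
) -> FeatureMatrix:
    """Assemble the 56-column predictor table for one measurement.

    ``raw`` must be the wheel stream for variant S1 and the frame stream for
    S2, on the same clock as ``kin``.  Segments labeled "unknown" are
    excluded (they carry no training target).
    """
    if variant not in ("S1", "S2"):
        raise ValueError(f"variant must be 'S1' or 'S2', got {variant!r}")
    expected_role = "wheel" if variant == "S1" else "frame"
    if raw.sensor_role != expected_role:
        raise ValueError(
            f"variant {variant} requires the {expected_role} sensor stream, "
            f"got {raw.sensor_role!r}"
        )
    if len(raw) != len(kin):
        raise ValueError("raw stream and kinematic series must share a clock")

    series = _segment_series(kin, raw)
    rows = []
    for seg in segments:
        if seg.label == "unknown":
            continue
        i, j = seg.sample_span
        row: dict[str, object] = {}
        _, amps = fft_amplitudes(kin.forward_speed[i:j], kin.sample_rate)
        for agg, val in zip(AGGREGATES, aggregate(amps)):
            row[f"speed_fft_{agg}"] = val
        for name, full in series.items():
            for agg, val in zip(AGGREGATES, aggregate(full[i:j])):
                row[f"{name}_{agg}"] = val
        row["y"] = 1 if seg.label == "active" else 0
        row["participant_id"] = seg.participant_id
        row["diagnosis"] = seg.diagnosis
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS + META_COLUMNS))
    return FeatureMatrix(data=df, variant=variant)


def prune_correlated(fm: FeatureMatrix, threshold: float = 0.7) -> list[str]:
    """Greedy multicollinearity pruning at |Pearson r| > threshold (strict).

    Zero-variance columns are dropped first; the rest are scanned in
    canonical order and a column is kept iff its absolute correlation with
    every already-kept column is <= threshold.  Returns the kept names in
    canonical order.
    """
    if len(fm) < 2:
        raise ValueError("pruning requires at least 2 rows")
    X = fm.predictors
    variances = X.var(ddof=0)
    candidates = [c for c in CANONICAL_COLUMNS if variances[c] > 0]
    corr = X[candidates].corr().abs()
    kept: list[str] = []
    for col in candidates:
        if all(corr.loc[col, k] <= threshold for k in kept):
            kept.append(col)
    return kept
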