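"""End-to-end orchestration: streams -> kinematics -> segments -> features -> report.

All randomness flows from a single root seed through named substreams
(simulator, splits, CV) so every stage is independently reproducible, and
intermediate artifacts (kinematics, segments, features, report, importance
table, manifest) can be persisted to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EvaluationReport, feature_importance, run_benchmark
from .features import CANONICAL_COLUMNS, FeatureMatrix, build_feature_matrix, prune_correlated
from .io import (
    AnnotationTrack,
    ImuStream,
    WheelchairGeometry,
    synchronize,
)
from .kinematics import (
    KinematicSeries,
    compute_kinematics,
    correct_gyro_offset,
    stationary_mask,
)
from .segmentation import Segment, SegmentationConfig, detect_segments, label_segments
from .simulate import NoiseModel, SimulatedTrial, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "process_trial",
    "cohort_feature_matrix",
    "run_end_to_end",
]


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run."""

    variants: tuple[str, ...] = ("S1", "S2")
    seed: int = 0
    n_participants: int = 24
    n_splits: int = 25
    pruning_threshold: float = 0.7
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    geometry: WheelchairGeometry = field(default_factory=WheelchairGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    distinguishable: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in ("S1", "S2"):
                raise ValueError(f"unknown variant {v!r}")


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    importances: dict[str, pd.DataFrame]
    features: dict[str, FeatureMatrix]
    segment_counts: dict[str, dict[str, int]]
    manifest: dict


def process_trial(
    wheel: ImuStream,
    frame: ImuStream | None,
    annotations: AnnotationTrack,
    geometry: WheelchairGeometry,
    variant: str,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[KinematicSeries, list[Segment], ImuStream]:
    """One measurement through sync, kinematics and labeled segmentation.

    Returns the kinematic series, labeled segments, and the offset-corrected
    raw stream feeding the variant's raw feature block, all on the shared
    clock.
    """
    if variant == "S2":
        if frame is None:
            raise ValueError("variant S2 requires a frame stream")
        wheel, frame = synchronize(wheel, frame)
        raw = correct_gyro_offset(frame, mask=stationary_mask(wheel))
    else:
        raw = correct_gyro_offset(wheel)
    kin = compute_kinematics(wheel, geometry, frame=frame, variant=variant)
    segments = label_segments(detect_segments(kin, seg_cfg), annotations)
    return kin, segments, raw


def cohort_feature_matrix(
    trials: list[SimulatedTrial],
    variant: str,
    geometry: WheelchairGeometry,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[FeatureMatrix, list[Segment]]:
    """Concatenate per-trial feature rows into one cohort matrix."""
    frames = []
    all_segments: list[Segment] = []
    for trial in trials:
        kin, segments, raw = process_trial(
            trial.wheel, trial.frame, trial.annotations, geometry, variant, seg_cfg
        )
        fm = build_feature_matrix(segments, kin, raw, variant)
        frames.append(fm.data)
        all_segments.extend(segments)
    data = pd.concat(frames, ignore_index=True)
    return FeatureMatrix(data=data, variant=variant), all_segments


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_end_to_end(cfg: PipelineConfig) -> PipelineResult:
    """Simulated cohort through the full chain for each requested variant."""
    ss = np.random.SeedSequence(cfg.seed)
    sim_seed, bench_seed, imp_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    logger.info("simulating cohort: %d participants", cfg.n_participants)
    trials = generate_cohort(
        n_participants=cfg.n_participants,
        seed=sim_seed,
        geometry=cfg.geometry,
        noise=cfg.noise,
        distinguishable=cfg.distinguishable,
    )
    reports: dict[str, EvaluationReport] = {}
    importances: dict[str, pd.DataFrame] = {}
    features: dict[str, FeatureMatrix] = {}
    seg_counts: dict[str, dict[str, int]] = {}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for variant in cfg.variants:
        fm, segments = cohort_feature_matrix(trials, variant, cfg.geometry, cfg.segmentation)
        labels = pd.Series([s.label for s in segments])
        seg_counts[variant] = {
            "total": len(segments),
            "active": int((labels == "active").sum()),
            "passive": int((labels == "passive").sum()),
            "unknown": int((labels == "unknown").sum()),
        }
        logger.info(
            "%s: %d segments (%d active / %d passive / %d unknown)",
            variant,
            *[seg_counts[variant][k] for k in ("total", "active", "passive", "unknown")],
        )
        retained = prune_correlated(fm, cfg.pruning_threshold)
        logger.info(
            "%s: %d of %d predictors retained after |r| > %.2f pruning",
            variant,
            len(retained),
            len(CANONICAL_COLUMNS),
            cfg.pruning_threshold,
        )
        report = run_benchmark(fm, columns=retained, n_splits=cfg.n_splits, seed=bench_seed)
        imp = feature_importance(fm, columns=retained, seed=imp_seed).to_frame()
        reports[variant] = report
        importances[variant] = imp
        features[variant] = fm
        if out:
            fm.data.to_csv(out / f"features_{variant}.csv", index=False)
            imp.to_csv(out / f"importance_{variant}.csv", index=False)
            (out / f"report_{variant}.json").write_text(json.dumps(report.to_dict(), indent=2))
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "n_splits": cfg.n_splits,
        "variants": list(cfg.variants),
    }
    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        reports=reports,
        importances=importances,
        features=features,
        segment_counts=seg_counts,
        manifest=manifest,
    )
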