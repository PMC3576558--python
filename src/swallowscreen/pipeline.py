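"""End-to-end orchestration: preprocess -> segment -> features -> LOO ->
rollup -> screening metrics.

The decomposition depth for denoising and feature extraction defaults to
``round(log2(fs/10))`` so the approximation band sits below ~5 Hz at any
sampling rate (L=10 at 10 kHz, L=7 at 1 kHz), keeping head-motion residuals
out of the vibration-band features.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from hashlib import sha256
from typing import Mapping

import pandas as pd

from . import classifier as clf
from . import features as feat
from . import metrics as met
from . import preprocess as pre
from . import segmentation as seg
from .signal_io import PasRating, Recording, SegmentBoundary

logger = logging.getLogger("swallowscreen")


def default_level(fs: float) -> int:
    """Decomposition depth putting the approximation band below ~5 Hz."""
    return max(1, round(math.log2(fs / 10.0)))


@dataclass
class RunConfig:
    """Knobs for one end-to-end run; ``None`` levels resolve from fs."""

    inverse_order: int = 10
    denoise_level: int | None = None
    feature_level: int | None = None
    knot_spacing_s: float = 0.5
    covariance: str = "per_class"
    shrinkage: float = 0.1
    seed: int = 0

    def config_hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True)
        return sha256(doc.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    results: list[clf.DeviceResult]
    metrics: dict[str, met.ScreeningMetrics]
    feature_table: pd.DataFrame
    truth: dict[tuple, str]
    config_hash: str = ""
    seed: int = 0


def evaluate_cohort(
    recordings: Mapping[tuple[str, str], Recording],
    boundaries: list[SegmentBoundary],
    ratings: list[PasRating],
    cfg: RunConfig = RunConfig(),
    calibration: Recording | None = None,
) -> RunResult:
    """Run the full screening pipeline on loaded data.

    Gold-standard labels come from the binary PAS collapse; the classifier
    is evaluated leave-one-out at the subswallow level and rolled up
    worst-case to bolus and participant resolution.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    fs = next(iter(recordings.values())).fs
    d_level = cfg.denoise_level or default_level(fs)
    f_level = cfg.feature_level or default_level(fs)

    inv = (
        pre.estimate_inverse_filter(calibration, cfg.inverse_order)
        if calibration is not None
        else pre.identity_filter()
    )
    dcfg = pre.DenoiseConfig(level=d_level)
    tcfg = pre.DetrendConfig(knot_spacing_s=cfg.knot_spacing_s)
    fcfg = feat.FeatureConfig(level=f_level)

    t0 = time.perf_counter()
    by_rec: dict[tuple[str, str], list[SegmentBoundary]] = {}
    for b in boundaries:
        by_rec.setdefault((b.participant_id, b.task_id), []).append(b)
    unknown = set(by_rec) - set(recordings)
    if unknown:
        raise ValueError(f"segment boundaries reference unknown recordings: {sorted(unknown)}")

    clips: list[seg.SwallowClip] = []
    for key in sorted(by_rec):
        processed = pre.preprocess_recording(recordings[key], inv, dcfg, tcfg)
        clips.extend(seg.extract_clips(processed, by_rec[key]))
    logger.info(
        "preprocess+segment: %d recordings -> %d clips in %.2fs",
        len(by_rec), len(clips), time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    table = feat.build_feature_table(clips, fcfg)
    logger.info("features: %d x %d in %.2fs", *table.shape, time.perf_counter() - t0)

    truth = {r.key: met.collapse_pas(r.score) for r in ratings}
    keys = [c.key for c in clips]
    missing = [k for k in keys if k not in truth]
    if missing:
        raise ValueError(f"{len(missing)} clip(s) without a PAS rating, e.g. {missing[0]}")

    names = fcfg.feature_names()
    X = table[names].to_numpy()
    y = pd.Series([truth[k] for k in keys]).to_numpy()

    t0 = time.perf_counter()
    results = clf.loo_evaluate(
        X, y, clf.ClassifierConfig(covariance=cfg.covariance, shrinkage=cfg.shrinkage),
        keys=keys, feature_names=names,
    )
    logger.info("LOO: %d folds in %.2fs", len(results), time.perf_counter() - t0)

    device = {r.key: r.label for r in results}
    metrics = met.metrics_at_all_resolutions(truth, device)
    return RunResult(
        results=results,
        metrics=metrics,
        feature_table=table,
        truth=truth,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
    )
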