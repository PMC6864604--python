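"""End-to-end orchestration: analyze -> calibrate -> classify, with config.

``RunConfig`` gathers every tunable of a full run — grid orientation, Otsu
settings, the regression reference quantity, SVM regularization, fold count
and seed, and the unit-conversion constants (sample volume, molecular
weight) — and round-trips through YAML so any report is regenerable from its
logged configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from os import PathLike
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import yaml

from .calibration import (
    CalibrationModel,
    Reading,
    class_stats,
    fit_calibration,
)
from .classify import accuracy, cross_validate, predict, train_svm
from .quantify import PipelineConfig, analyze_strip
from .image_io import read_image

logger = logging.getLogger("lfaquant")

__all__ = ["RunConfig", "run_end_to_end", "analyze_images", "synthetic_readings"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration with file round-trip."""

    flipped: bool = False
    otsu_levels: int = 2
    mask_whole_image: bool = False
    reference_quantity_fg: float = 10.0
    svm_c: float = 1.0
    cv_folds: int = 5
    seed: int = 0
    sample_volume_ul: float = 10.0
    molecular_weight_g_mol: Optional[float] = None

    @property
    def image_config(self) -> PipelineConfig:
        return PipelineConfig(
            flipped=self.flipped,
            otsu_levels=self.otsu_levels,
            mask_whole_image=self.mask_whole_image,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    @classmethod
    def load(cls, path: Union[str, PathLike]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def analyze_images(
    paths: Sequence[Union[str, PathLike]], config: Optional[RunConfig] = None
) -> List[dict]:
    """Run the strip readout on each image file, returning summary dicts."""
    cfg = config or RunConfig()
    out = []
    for p in paths:
        summary = analyze_strip(read_image(p), cfg.image_config)
        logger.info("analyzed %s: T/C=%.4f TH=%.4f", p, summary.tc_ratio, summary.threshold)
        out.append({"path": str(p), **summary.to_dict()})
    return out


def synthetic_readings(
    quantities_fg: Sequence[float],
    model: CalibrationModel,
    n_per_quantity: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> List[Reading]:
    """Generate and read out synthetic strips for the given quantity classes.

    Each strip's test-line strength is chosen so its noiseless T/C matches the
    calibration line at that quantity; replicate strips differ only in their
    noise seed (and are identical when ``noise_sd`` is 0).
    """
    from .synthetic import SyntheticStripSpec, generate_strip, strength_for_quantity

    cfg = config or RunConfig()
    readings: List[Reading] = []
    for qi, q in enumerate(quantities_fg):
        strength = strength_for_quantity(q, model)
        for rep in range(n_per_quantity):
            spec = SyntheticStripSpec(
                test_strength=strength,
                noise_sd=noise_sd,
                seed=seed + 1000 * qi + rep,
                flipped=cfg.flipped,
            )
            img, _ = generate_strip(spec)
            summary = analyze_strip(img, cfg.image_config)
            readings.append(
                Reading(set_id=0, quantity_fg=q, tc_ratio=summary.tc_ratio,
                        reading_index=rep + 1)
            )
    return readings


def run_end_to_end(
    readings: Iterable[Reading], config: Optional[RunConfig] = None
) -> Dict:
    """Calibrate on labelled readings and cross-validate the SVM classifier.

    Returns a JSON-ready report with the calibration line, its figures of
    merit, per-class statistics and the pooled cross-validation confusion
    matrix. Raises on empty input.
    """
    cfg = config or RunConfig()
    readings = list(readings)
    if not readings:
        raise ValueError("no readings supplied")
    logger.info("fitting calibration on %d readings", len(readings))
    model, diag = fit_calibration(
        readings, reference_quantity_fg=cfg.reference_quantity_fg
    )
    logger.info(
        "calibration: m=%.4f b=%.4f R2=%.4f sigma=%.4f",
        model.slope, model.intercept, model.r2, model.sigma,
    )
    stats = class_stats(readings)
    features = [(r.tc_ratio - model.intercept) / model.slope for r in readings]
    labels = [r.quantity_fg for r in readings]
    cm = cross_validate(features, labels, k=cfg.cv_folds, seed=cfg.seed, C=cfg.svm_c)
    acc = accuracy(cm)
    logger.info("%d-fold CV accuracy: %.1f%%", cfg.cv_folds, acc)
    return {
        "n_readings": len(readings),
        "calibration": {
            "slope": model.slope,
            "intercept": model.intercept,
            "r2": model.r2,
            "sigma": model.sigma,
            "lod_x": model.lod_x,
            "loq_x": model.loq_x,
        },
        "class_stats": [
            {
                "quantity_fg": s.quantity_fg,
                "mean": s.mean,
                "std": s.std,
                "cv_percent": s.cv_percent,
                "n": s.n,
            }
            for s in stats
        ],
        "confusion_matrix": cm.to_dict(),
        "accuracy_percent": acc,
        "config": asdict(cfg),
    }
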