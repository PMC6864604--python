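"""Weighted red-intensity sums and the T/C ratio.

The signal of a line region is the sum of red-channel intensities over its
masked pixels, S_region = sum I_R(x, y). The readout feature is the ratio
of the test-line signal to the control-line signal,

    T/C = S_test / S_control,

which cancels global illumination scaling and is the quantity calibrated
against analyte mass. An absent control line (S_control = 0) means the assay
did not run and the strip is invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidStripError
from .image_io import RGBImage
from .roi import Rect, RegionPair, center_box, line_regions
from .segmentation import Mask, build_mask, ratio_image

__all__ = ["PipelineConfig", "IntensitySummary", "weighted_sum", "tc_ratio", "analyze_strip"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the image-analysis pipeline.

    flipped: control line in the lower (instead of upper) band of the center cell.
    otsu_levels: class count for the Otsu search (the top threshold is used).
    mask_whole_image: apply TH_mask to the full frame rather than only the
        line regions; the sums are restricted to the line regions either way.
    """

    flipped: bool = False
    otsu_levels: int = 2
    mask_whole_image: bool = False

    def to_dict(self) -> dict:
        return {
            "flipped": self.flipped,
            "otsu_levels": self.otsu_levels,
            "mask_whole_image": self.mask_whole_image,
        }


@dataclass(frozen=True)
class IntensitySummary:
    """Per-strip readout: region signals, their ratio and diagnostics."""

    s_test: int
    s_control: int
    tc_ratio: float
    threshold: float
    regions: RegionPair
    masked_pixels_test: int
    masked_pixels_control: int
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        return {
            "s_test": self.s_test,
            "s_control": self.s_control,
            "tc_ratio": self.tc_ratio,
            "th_mask": self.threshold,
            "test_rect": self.regions.test.to_dict(),
            "control_rect": self.regions.control.to_dict(),
            "masked_pixels_test": self.masked_pixels_test,
            "masked_pixels_control": self.masked_pixels_control,
            "config": self.config.to_dict(),
        }


def weighted_sum(img: RGBImage, mask: Mask, region: Rect) -> int:
    """Sum of red intensities over masked pixels of ``region``."""
    if mask.values.shape != img.red.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match image {img.red.shape}"
        )
    sl = region.slices
    red = img.red[sl].astype(np.int64)
    return int((red * mask.values[sl]).sum())


def tc_ratio(s_test: float, s_control: float) -> float:
    """Test-to-control signal ratio; errors when the control line is absent."""
    if s_control <= 0:
        raise InvalidStripError(
            "control-line signal is zero: the control line is absent, assay invalid"
        )
    return s_test / s_control


def analyze_strip(img: RGBImage, config: Optional[PipelineConfig] = None) -> IntensitySummary:
    """Full readout of one strip image.

    Deterministic composition: center cell -> line regions -> ratio image ->
    Otsu mask on the control region -> weighted red sums -> T/C ratio.
    """
    cfg = config or PipelineConfig()
    center = center_box(img.width, img.height)
    regions = line_regions(center, flipped=cfg.flipped)
    r = ratio_image(img)
    apply_to = None if cfg.mask_whole_image else [regions.control, regions.test]
    mask = build_mask(r, regions.control, apply_to=apply_to, levels=cfg.otsu_levels)
    s_control = weighted_sum(img, mask, regions.control)
    s_test = weighted_sum(img, mask, regions.test)
    return IntensitySummary(
        s_test=s_test,
        s_control=s_control,
        tc_ratio=tc_ratio(s_test, s_control),
        threshold=mask.threshold,
        regions=regions,
        masked_pixels_test=mask.count(regions.test),
        masked_pixels_control=mask.count(regions.control),
        config=cfg,
    )
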