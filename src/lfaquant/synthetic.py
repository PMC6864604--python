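"""Seeded synthetic LFA strip images with known ground truth.

The generator realizes the forward model the readout assumes: a bright
uniform background, a fully developed reddish control line in the upper band
of the center grid cell, and a test line in the middle band whose developed
extent grows with analyte quantity. "Strength" is the developed coverage of
a line: the fraction of the band rectangle that is painted at the full band
color (a centered sub-rectangle). With both lines sharing one band color,
the pipeline's T/C ratio equals the ratio of painted areas — spanning [0, 1],
strictly monotone in test strength, and exactly invariant under global
illumination scaling because the shared painted intensity cancels even after
8-bit quantization.

After painting, all channels are multiplied by the illumination factor k,
independent Gaussian noise is added per pixel and channel, and the result is
rounded and clipped to [0, 255]. Identical specs and seeds give byte-identical
images. Note that k > 1 may clip painted or background values at 255, which
voids the illumination-invariance property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .calibration import CalibrationModel
from .errors import CalibrationRangeError, GeometryError
from .image_io import RGBImage
from .quantify import PipelineConfig, analyze_strip
from .roi import Rect, center_box, line_regions

__all__ = ["SyntheticStripSpec", "GroundTruth", "generate_strip", "strength_for_quantity"]

Color = Tuple[int, int, int]


@dataclass(frozen=True)
class SyntheticStripSpec:
    """Parameters of one synthetic strip image.

    Defaults emulate the intensity regime of real strips: background gray
    near 200 in all channels (ratio ~ 1) and line color (160, 130, 130),
    i.e. red/green ratio ~ 1.23 inside the lines. ``band_thickness`` is a
    fraction of the center-cell height; the painted band is centered within
    its third of the cell. ``noise_sd`` defaults to a light sensor-like
    2 intensity levels; set 0 for exact, noiseless geometry.
    """

    width: int = 300
    height: int = 300
    background: Color = (200, 200, 200)
    control_color: Color = (160, 130, 130)
    test_color: Color = (160, 130, 130)
    control_strength: float = 1.0
    test_strength: float = 0.5
    band_thickness: float = 0.2
    illumination: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0
    flipped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_strength <= 1.0:
            raise ValueError(f"control_strength {self.control_strength} outside [0, 1]")
        if not 0.0 <= self.test_strength <= 1.0:
            raise ValueError(f"test_strength {self.test_strength} outside [0, 1]")
        if self.illumination <= 0:
            raise ValueError(f"illumination {self.illumination} must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd {self.noise_sd} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Where the lines were painted, echoed with the generating spec."""

    control_rect: Optional[Rect]
    test_rect: Optional[Rect]
    spec: SyntheticStripSpec
    expected_tc_ratio: float

    def to_json(self) -> str:
        d: Dict = {
            "control_rect": self.control_rect.to_dict() if self.control_rect else None,
            "test_rect": self.test_rect.to_dict() if self.test_rect else None,
            "expected_tc_ratio": self.expected_tc_ratio,
            "spec": {
                **{
                    k: getattr(self.spec, k)
                    for k in (
                        "width", "height", "control_strength", "test_strength",
                        "band_thickness", "illumination", "noise_sd", "seed", "flipped",
                    )
                },
                "background": list(self.spec.background),
                "control_color": list(self.spec.control_color),
                "test_color": list(self.spec.test_color),
            },
        }
        return json.dumps(d, indent=2)


def _painted_rect(band: Rect, strength: float, thickness_px: int) -> Optional[Rect]:
    """Centered sub-rectangle covering ``strength`` of the band width, or None."""
    wpx = int(round(strength * band.width))
    if wpx == 0 or thickness_px == 0:
        return None
    x0 = band.x0 + (band.width - wpx) // 2
    y0 = band.y0 + (band.height - thickness_px) // 2
    return Rect(x0, y0, x0 + wpx, y0 + thickness_px)


def generate_strip(spec: SyntheticStripSpec) -> Tuple[RGBImage, GroundTruth]:
    """Render a synthetic strip and report its painted-line ground truth."""
    center = center_box(spec.width, spec.height)
    regions = line_regions(center, flipped=spec.flipped)
    thickness_px = int(round(spec.band_thickness * center.height))
    for band in (regions.control, regions.test):
        if thickness_px > band.height:
            raise GeometryError(
                f"band thickness {thickness_px}px exceeds its {band.height}px "
                "third of the center cell"
            )

    scene = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    scene[:, :] = spec.background
    control_rect = _painted_rect(regions.control, spec.control_strength, thickness_px)
    test_rect = _painted_rect(regions.test, spec.test_strength, thickness_px)
    if control_rect is not None:
        scene[control_rect.slices] = spec.control_color
    if test_rect is not None:
        scene[test_rect.slices] = spec.test_color

    scene *= spec.illumination
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        scene += rng.normal(0.0, spec.noise_sd, size=scene.shape)
    arr = np.clip(np.rint(scene), 0, 255).astype(np.uint8)

    img = RGBImage(
        alpha=np.full((spec.height, spec.width), 255, dtype=np.uint8),
        red=arr[:, :, 0],
        green=arr[:, :, 1],
        blue=arr[:, :, 2],
    )
    n_test = test_rect.area if test_rect else 0
    n_control = control_rect.area if control_rect else 0
    expected_tc = n_test / n_control if n_control else float("nan")
    return img, GroundTruth(
        control_rect=control_rect,
        test_rect=test_rect,
        spec=spec,
        expected_tc_ratio=expected_tc,
    )


_RESPONSE_CACHE: Dict[SyntheticStripSpec, Tuple[np.ndarray, np.ndarray]] = {}


def _response_curve(template: SyntheticStripSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless pipeline T/C as a function of test strength, on a 0..1 grid."""
    key = replace(template, test_strength=0.0, noise_sd=0.0, illumination=1.0)
    if key in _RESPONSE_CACHE:
        return _RESPONSE_CACHE[key]
    strengths = np.linspace(0.0, 1.0, 101)
    cfg = PipelineConfig(flipped=template.flipped)
    tcs = np.empty_like(strengths)
    for i, s in enumerate(strengths):
        img, _ = generate_strip(replace(key, test_strength=float(s)))
        tcs[i] = analyze_strip(img, cfg).tc_ratio
    # enforce non-decreasing for a well-defined inverse (rounding plateaus only)
    tcs = np.maximum.accumulate(tcs)
    _RESPONSE_CACHE[key] = (strengths, tcs)
    return strengths, tcs


def strength_for_quantity(
    quantity_fg: float,
    model: CalibrationModel,
    template: Optional[SyntheticStripSpec] = None,
) -> float:
    """Test-line strength whose noiseless pipeline T/C matches the calibrated value.

    The target is the calibration line evaluated at x = log10(quantity / 10 fg);
    it is inverted through a lookup of the actual pipeline response built for
    the (default) generator geometry, so the returned strength reproduces the
    target T/C to within the response grid's resolution (~0.01).
    """
    if quantity_fg <= 0:
        raise ValueError(f"quantity must be > 0 fg, got {quantity_fg}")
    if model.slope < 0:
        raise ValueError(f"calibration slope must be >= 0, got {model.slope}")
    template = template or SyntheticStripSpec()
    x = np.log10(quantity_fg / model.reference_quantity_fg)
    target = model.slope * x + model.intercept
    strengths, tcs = _response_curve(template)
    if not (tcs[0] - 1e-9 <= target <= tcs[-1] + 1e-9):
        raise CalibrationRangeError(
            f"target T/C {target:.4f} outside achievable range "
            f"[{tcs[0]:.4f}, {tcs[-1]:.4f}]"
        )
    return float(np.interp(target, tcs, strengths))
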