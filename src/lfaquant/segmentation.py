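"""Red/green-ratio segmentation of test and control lines.

On a white-backed strip, the red and green intensities of background pixels
are nearly equal (ratio ~ 1), while colloidal-gold lines absorb green more
strongly than red, so their red/green ratio stands well above unity. A
threshold TH_mask on the ratio image, chosen by Otsu's criterion on the
control-line region, yields the binary mask

    mask(x, y) = 1  iff  I_R(x, y) / I_G(x, y) > TH_mask

(strict inequality; pixels with I_G = 0 are invalid and never masked).

The Otsu search here follows the 8-bit convention adapted to real-valued
ratios: 256 uniform histogram bins spanning the observed value range, with
candidate thresholds at interior bin edges and ties broken toward the
smallest threshold. The multilevel generalisation returns ``levels - 1``
ascending thresholds; the pipeline uses levels = 2 (one threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError
from .image_io import RGBImage
from .roi import Rect

__all__ = ["RatioImage", "Mask", "ratio_image", "otsu_threshold", "build_mask"]

N_BINS = 256


@dataclass(frozen=True)
class RatioImage:
    """Per-pixel red/green intensity ratio with a validity plane.

    ``valid`` is False where the green intensity is zero (ratio undefined);
    invalid pixels carry ratio 0 and are excluded from histograms and masks.
    """

    ratio: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.ratio.shape

    def region_values(self, region: Rect) -> np.ndarray:
        """Valid ratio values inside ``region``, flattened."""
        r = self.ratio[region.slices]
        v = self.valid[region.slices]
        return r[v]


@dataclass(frozen=True)
class Mask:
    """Binary segmentation mask and the ratio threshold that produced it."""

    values: np.ndarray  # uint8, exactly 0 or 1, full image dimensions
    threshold: float

    def count(self, region: Optional[Rect] = None) -> int:
        if region is None:
            return int(self.values.sum())
        return int(self.values[region.slices].sum())

    def to_png_array(self) -> np.ndarray:
        """Render the mask as a 0/255 grayscale array for visual inspection."""
        return (self.values * np.uint8(255)).astype(np.uint8)


def ratio_image(img: RGBImage) -> RatioImage:
    """Compute the elementwise red/green ratio plane of an image."""
    red = img.red.astype(np.float64)
    green = img.green.astype(np.float64)
    valid = img.green > 0
    ratio = np.zeros_like(red)
    np.divide(red, green, out=ratio, where=valid)
    return RatioImage(ratio=ratio, valid=valid)


def _intra_class_variance(counts: np.ndarray, centers: np.ndarray, cuts: Tuple[int, ...]) -> float:
    """Total weighted intra-class variance for classes delimited at bin ``cuts``."""
    total = 0.0
    bounds = (0, *cuts, len(counts))
    n = counts.sum()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        w = counts[lo:hi].sum()
        if w == 0:
            continue
        c = centers[lo:hi]
        p = counts[lo:hi] / w
        mean = float(p @ c)
        var = float(p @ (c - mean) ** 2)
        total += (w / n) * var
    return total


def otsu_threshold(values: Sequence[float], levels: int = 2) -> np.ndarray:
    """Otsu threshold(s) of a value collection, minimizing intra-class variance.

    The histogram has 256 uniform bins over ``[min(values), max(values)]``;
    thresholds are returned as interior bin-edge values, ascending. For
    ``levels=2`` the search is exhaustive over all 255 candidate cuts; for
    higher level counts all cut combinations are enumerated. When several
    cuts tie, the smallest thresholds win.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if vals.size < 2:
        raise DegenerateInputError("need at least 2 values to threshold")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise DegenerateInputError("all values identical; no threshold exists")
    counts, edges = np.histogram(vals, bins=N_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    best_cuts: Optional[Tuple[int, ...]] = None
    best_var = np.inf
    # Candidate cuts are interior bin boundaries 1..N_BINS-1; lexicographically
    # increasing enumeration + strict improvement gives smallest-threshold ties.
    for cuts in combinations(range(1, N_BINS), levels - 1):
        v = _intra_class_variance(counts, centers, cuts)
        if v < best_var - 1e-15:
            best_var = v
            best_cuts = cuts
    assert best_cuts is not None
    return edges[np.array(best_cuts)]


def build_mask(
    r: RatioImage,
    region_for_threshold: Rect,
    apply_to: Optional[Sequence[Rect]] = None,
    levels: int = 2,
) -> Mask:
    """Threshold the ratio image with Otsu on the control region and apply Eq-style masking.

    TH_mask is the top threshold from :func:`otsu_threshold` on the valid
    ratios inside ``region_for_threshold``. The binary mask is 1 exactly where
    a pixel is valid, lies inside one of the ``apply_to`` rectangles (the whole
    image when ``apply_to`` is None), and its ratio strictly exceeds TH_mask.
    """
    region_vals = r.region_values(region_for_threshold)
    thresholds = otsu_threshold(region_vals, levels=levels)
    th_mask = float(thresholds[-1])

    above = (r.ratio > th_mask) & r.valid
    if apply_to is None:
        values = above.astype(np.uint8)
    else:
        values = np.zeros(r.shape, dtype=np.uint8)
        for rect in apply_to:
            sl = rect.slices
            values[sl] = above[sl]
    return Mask(values=values, threshold=th_mask)
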