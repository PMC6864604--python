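"""Region-of-interest geometry: the 3x3 viewfinder grid and line regions.

The capture protocol frames the strip so its read window sits exactly in the
center cell of the camera's 3x3 grid. The center cell is then subdivided into
three equal horizontal bands; the control line occupies one outer band and
the test line the middle band. Coordinates are 0-based with x = column,
y = row, origin top-left; rectangles are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError

__all__ = ["Rect", "RegionPair", "center_box", "line_regions"]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise GeometryError(f"degenerate rectangle {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def slices(self):
        """Numpy row/column slices selecting this rectangle from an image array."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def contains(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}


@dataclass(frozen=True)
class RegionPair:
    """The control-line and test-line rectangles inside the center cell."""

    control: Rect
    test: Rect


def center_box(width: int, height: int) -> Rect:
    """Return the middle ninth of a ``width x height`` image.

    Uses floor division: ``x in [w//3, 2w//3)``, ``y in [h//3, 2h//3)``.
    """
    if width < 3 or height < 3:
        raise GeometryError(
            f"image {width}x{height} too small for a 3x3 grid (need >= 3 in each dimension)"
        )
    return Rect(width // 3, height // 3, 2 * width // 3, 2 * height // 3)


def line_regions(center: Rect, flipped: bool = False) -> RegionPair:
    """Split the center cell into thirds and return the control/test bands.

    The cell's inner y-axis is divided at lattice points 0..3 by floor splits
    (remainder rows go to the last band); each band spans the full cell width.
    The test line is always the middle band. By default the control line is the
    upper band; ``flipped=True`` places it in the lower band instead, for strips
    framed with the sample pad at the top.
    """
    if center.height < 3:
        raise GeometryError(f"center box height {center.height} < 3, cannot form bands")
    y_a = center.y0 + center.height // 3
    y_b = center.y0 + 2 * center.height // 3
    upper = Rect(center.x0, center.y0, center.x1, y_a)
    middle = Rect(center.x0, y_a, center.x1, y_b)
    lower = Rect(center.x0, y_b, center.x1, center.y1)
    return RegionPair(control=lower if flipped else upper, test=middle)
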