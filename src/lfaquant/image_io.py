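"""8-bit ARGB raster images: reading, writing and the 32-bit pixel layout.

The readout pipeline operates on four 8-bit channel planes (alpha, red,
green, blue), matching the 32-bit ARGB pixel format produced by smartphone
cameras: bits 31-24 alpha, 23-16 red, 15-8 green, 7-0 blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Tuple, Union

import imageio.v3 as iio
import numpy as np

from .errors import UnsupportedFormatError

PathType = Union[str, PathLike]

__all__ = ["RGBImage", "pack_argb", "unpack_argb", "read_image", "write_image"]


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit four-plane raster (alpha, red, green, blue).

    All planes are ``uint8`` arrays of identical ``(height, width)`` shape;
    intensities therefore lie in [0, 255] by construction.
    """

    alpha: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        shapes = {p.shape for p in (self.alpha, self.red, self.green, self.blue)}
        if len(shapes) != 1:
            raise ValueError(f"channel planes differ in shape: {shapes}")
        for name in ("alpha", "red", "green", "blue"):
            plane = getattr(self, name)
            if plane.ndim != 2:
                raise ValueError(f"{name} plane must be 2-D, got {plane.ndim}-D")
            if plane.dtype != np.uint8:
                raise ValueError(f"{name} plane must be uint8, got {plane.dtype}")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RGBImage":
        """Build from an ``(H, W)``, ``(H, W, 3)`` RGB or ``(H, W, 4)`` RGBA uint8 array.

        Grayscale is broadcast to all color channels; a missing alpha channel
        is filled with 255 (fully opaque).
        """
        if arr.dtype != np.uint8:
            raise UnsupportedFormatError(
                f"only 8-bit/channel images are supported, got dtype {arr.dtype}"
            )
        if arr.ndim == 2:
            arr = np.stack([arr, arr, arr], axis=-1)
        if arr.ndim != 3 or arr.shape[2] not in (3, 4):
            raise UnsupportedFormatError(
                f"expected gray/RGB/RGBA image, got shape {arr.shape}"
            )
        if arr.shape[2] == 3:
            alpha = np.full(arr.shape[:2], 255, dtype=np.uint8)
        else:
            alpha = arr[:, :, 3].copy()
        return cls(
            alpha=alpha,
            red=arr[:, :, 0].copy(),
            green=arr[:, :, 1].copy(),
            blue=arr[:, :, 2].copy(),
        )

    def to_rgba_array(self) -> np.ndarray:
        """Return an ``(H, W, 4)`` RGBA uint8 array (channel order R, G, B, A)."""
        return np.stack([self.red, self.green, self.blue, self.alpha], axis=-1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RGBImage):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in ("alpha", "red", "green", "blue")
        )


def pack_argb(alpha: int, red: int, green: int, blue: int) -> int:
    """Pack four 8-bit channel intensities into one 32-bit ARGB value."""
    for name, v in (("alpha", alpha), ("red", red), ("green", green), ("blue", blue)):
        if not 0 <= v <= 255:
            raise ValueError(f"{name} intensity {v} outside [0, 255]")
    return (alpha << 24) | (red << 16) | (green << 8) | blue


def unpack_argb(value: int) -> Tuple[int, int, int, int]:
    """Unpack a 32-bit ARGB value into (alpha, red, green, blue)."""
    if not 0 <= value < 2**32:
        raise ValueError(f"pixel value {value} outside [0, 2^32)")
    return (
        (value >> 24) & 0xFF,
        (value >> 16) & 0xFF,
        (value >> 8) & 0xFF,
        value & 0xFF,
    )


def read_image(path: PathType) -> RGBImage:
    """Read a PNG/TIFF/JPEG file into an :class:`RGBImage`.

    Images without an alpha channel get alpha filled with 255. Bit depths
    other than 8 bits per channel raise :class:`UnsupportedFormatError`.
    """
    arr = iio.imread(path)
    return RGBImage.from_array(np.asarray(arr))


def write_image(img: RGBImage, path: PathType) -> None:
    """Write an :class:`RGBImage` as RGBA. PNG and TIFF round-trip losslessly."""
    iio.imwrite(path, img.to_rgba_array())
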