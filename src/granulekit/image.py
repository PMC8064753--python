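"""Shared 2D image container and TIFF I/O.

Every detector and measurement in the package consumes :class:`ImageField`,
a thin wrapper around a single-channel 2D intensity grid that carries the
physical pixel size, a channel label, and the acquisition bit depth.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  coordinates;
* intensity grids are non-negative and finite;
* multi-frame data (time-lapses, z-stacks) are ordered lists of fields or
  3D ``(frame, row, col)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageField", "read_tiff", "write_tiff", "as_stack"]

#: physical pixel size of the acquisitions being emulated, in micrometers
DEFAULT_PIXEL_SIZE = 0.043


@dataclass
class ImageField:
    """A single-channel 2D intensity image with acquisition metadata.

    Parameters
    ----------
    data : ndarray
        2D non-negative, finite intensity grid.
    pixel_size : float
        Physical size of one pixel in micrometers.
    channel : str
        Free-form channel label (e.g. ``"Me31B-GFP"``, ``"smFISH"``).
    bit_depth : int
        16 or 32; the nominal depth of the acquisition.
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ImageField.data must be 2D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageField.data must be finite")
        if np.any(self.data < 0):
            raise ValueError("ImageField.data must be non-negative")
        if self.bit_depth not in (16, 32):
            raise ValueError(f"bit_depth must be 16 or 32, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype(self, dtype) -> "ImageField":
        return replace(self, data=self.data.astype(dtype))

    def crop(self, row0: int, col0: int, height: int, width: int) -> "ImageField":
        """Return the sub-field ``[row0:row0+height, col0:col0+width]``.

        Raises ``ValueError`` when the box is not fully inside the field.
        """
        h, w = self.shape
        if row0 < 0 or col0 < 0 or row0 + height > h or col0 + width > w or height <= 0 or width <= 0:
            raise ValueError(
                f"crop box ({row0},{col0},{height},{width}) outside field of shape {self.shape}"
            )
        return replace(self, data=self.data[row0 : row0 + height, col0 : col0 + width].copy())


def as_stack(frames: Sequence[ImageField] | np.ndarray) -> np.ndarray:
    """Stack frames into a 3D ``(frame, row, col)`` float array."""
    if isinstance(frames, np.ndarray):
        if frames.ndim != 3:
            raise ValueError("stack array must be 3D (frame, row, col)")
        return frames.astype(float)
    return np.stack([np.asarray(f.data, dtype=float) for f in frames])


def read_tiff(path, pixel_size: float = DEFAULT_PIXEL_SIZE, channel: str = "") -> ImageField | list[ImageField]:
    """Read a single-page TIFF as one field, or a multi-page TIFF as a list."""
    arr = tifffile.imread(path)
    bit_depth = 32 if arr.dtype.itemsize >= 4 else 16
    if arr.ndim == 2:
        return ImageField(arr, pixel_size=pixel_size, channel=channel, bit_depth=bit_depth)
    if arr.ndim == 3:
        return [
            ImageField(page, pixel_size=pixel_size, channel=channel, bit_depth=bit_depth)
            for page in arr
        ]
    raise ValueError(f"unsupported TIFF dimensionality: {arr.ndim}")


def write_tiff(path, fields: ImageField | Sequence[ImageField]) -> None:
    """Write one field (single page) or a sequence (multi-page time-lapse)."""
    if isinstance(fields, ImageField):
        tifffile.imwrite(path, fields.data)
    else:
        tifffile.imwrite(path, np.stack([f.data for f in fields]))
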