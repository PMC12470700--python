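"""The in-memory image container used throughout the package.

Radiographs are single-channel intensity grids.  ``ImageGrid`` wraps a 2-D
float64 array together with the nominal bit depth of the acquisition (8 or
16 bit), which fixes the dynamic range used by histogram-based metrics and
by export.  Pixel values are held as floats so that intermediate results
(smoothed images, residuals) lose no precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

_VALID_DEPTHS = (8, 16)


@dataclass
class ImageGrid:
    """A 2-D grid of finite, non-negative pixel intensities.

    Parameters
    ----------
    pixels:
        2-D array-like of intensities.  Stored as float64.
    bit_depth:
        Nominal acquisition depth, 8 or 16.  Values must not exceed
        ``2**bit_depth - 1``.
    source:
        Optional provenance string (file path, generator description).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidInputError(
                f"image must be a non-empty 2-D grid, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("image contains non-finite pixels")
        if arr.min() < 0:
            raise InvalidInputError("image contains negative pixels")
        if self.bit_depth not in _VALID_DEPTHS:
            raise InvalidInputError(
                f"bit_depth must be one of {_VALID_DEPTHS}, got {self.bit_depth}"
            )
        if arr.max() > self.nominal_max:
            raise InvalidInputError(
                f"pixel values exceed the {self.bit_depth}-bit range "
                f"[0, {self.nominal_max}]"
            )
        self.pixels = arr

    @property
    def nominal_max(self) -> float:
        """Top of the nominal dynamic range, ``2**bit_depth - 1``."""
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, source: str | None = None) -> "ImageGrid":
        """A new grid with the same bit depth but different pixel data."""
        return ImageGrid(pixels, bit_depth=self.bit_depth,
                         source=source if source is not None else self.source)


def as_grid(image, bit_depth: int = 8) -> ImageGrid:
    """Coerce an array or ImageGrid to an ImageGrid."""
    if isinstance(image, ImageGrid):
        return image
    return ImageGrid(np.asarray(image, dtype=np.float64), bit_depth=bit_depth)
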