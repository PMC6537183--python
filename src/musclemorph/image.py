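"""Core raster container shared by every pipeline stage.

All processing operates on single-channel grayscale rasters carrying their
bit depth and a physical pixel calibration (default 0.647 um/pixel, the
value obtained by calibrating a x10 objective against a precision ruler).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default physical calibration, micrometres per pixel edge.
DEFAULT_PIXEL_SIZE_UM = 0.647


@dataclass
class IntensityImage:
    """A single-channel 2-D grayscale raster with physical calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative raster.  Integer dtypes are the norm (8- or 16-bit
        microscope output); float rasters are accepted for intermediates.
    bit_depth : int
        Nominal bit depth of the container (not the camera dynamic range:
        a 12-bit camera saved in 16-bit TIFF has ``bit_depth == 16``).
    pixel_size_um : float
        Micrometres per pixel edge.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth: {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if px.min() < 0:
            raise ValueError("pixel values must be non-negative")
        if np.issubdtype(px.dtype, np.integer) and px.max() > self.max_value:
            raise ValueError(
                f"pixel values exceed 2^{self.bit_depth} - 1 ({self.max_value})"
            )
        self.pixels = px

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "IntensityImage":
        """Copy of this image with a new raster, same metadata."""
        return replace(self, pixels=pixels)
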