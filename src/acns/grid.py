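"""2-D intensity grids.

The whole pipeline works on single-channel 2-D images with an explicit
intensity ceiling (``MAX``). Values are carried as float64 internally;
quantization to the declared bit depth happens only on export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "as_values", "quantize"]


@dataclass
class ImageGrid:
    """A 2-D grayscale image with a declared intensity ceiling.

    Parameters
    ----------
    values : ndarray
        2-D array, row-major, origin at the top-left, 0-based indices.
    max_intensity : float
        Intensity ceiling MAX (255 for 8-bit data).
    bit_depth : int
        Bits per pixel of the source/export representation.
    """

    values: np.ndarray
    max_intensity: float = 255.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """A new grid sharing this grid's intensity convention."""
        return ImageGrid(values, self.max_intensity, self.bit_depth)

    def quantized(self) -> np.ndarray:
        """Integer-valued array: clip to [0, MAX], round half away from zero."""
        return quantize(self.values, self.max_intensity)


def as_values(image) -> np.ndarray:
    """Accept an ImageGrid or a bare 2-D array; return the float64 array."""
    if isinstance(image, ImageGrid):
        return image.values
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


def quantize(values: np.ndarray, max_intensity: float = 255.0) -> np.ndarray:
    """Clip to [0, MAX] and round half away from zero (export convention)."""
    clipped = np.clip(values, 0.0, max_intensity)
    return np.floor(clipped + 0.5)
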