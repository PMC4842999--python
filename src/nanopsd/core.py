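"""Shared primitives: physical-unit conversions and the in-memory image container.

Conventions used throughout the package:

* all lengths are nanometres unless a name says otherwise;
* image coordinates have the origin at the field's top-left corner, x
  rightward, y downward; pixel (row 0, col 0) covers the half-open square
  ``[0, pixel_size) x [0, pixel_size)`` so its centre sits at
  ``(pixel_size / 2, pixel_size / 2)``;
* Gaussian widths quoted as a full width at half maximum (FWHM) convert to a
  standard deviation through ``FWHM = 2 sqrt(2 ln 2) * sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: FWHM of a Gaussian divided by its standard deviation.
FWHM_PER_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to a standard deviation."""
    return float(fwhm) / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian standard deviation to a full width at half maximum."""
    return float(sigma) * FWHM_PER_SIGMA


@dataclass
class RenderedImage:
    """A single-channel 2D raster with a physical pixel size.

    Parameters
    ----------
    data:
        2D array, row-major (y, x).
    pixel_size:
        Edge length of one pixel in nm.
    channel:
        Free-form label, e.g. ``"confocal"``, ``"sted"``, ``"nn"``.
    """

    data: np.ndarray
    pixel_size: float
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def height_nm(self) -> float:
        return self.data.shape[0] * self.pixel_size

    @property
    def width_nm(self) -> float:
        return self.data.shape[1] * self.pixel_size

    def copy_with(self, data: np.ndarray) -> "RenderedImage":
        """New image sharing pixel size and channel label, with other data."""
        return RenderedImage(data=data, pixel_size=self.pixel_size,
                             channel=self.channel, meta=dict(self.meta))
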