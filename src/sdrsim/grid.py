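"""Pixel raster with physical coordinates.

All images in the package live on a :class:`Grid2D`: a raster of square
pixels of known physical size. The origin of the physical coordinate frame
is the geometric center pixel ``(n_rows // 2, n_cols // 2)``; pixel
``(i, j)`` sits at ``x = (j - j0) * pixel_size_nm`` (rightward) and
``y = (i - i0) * pixel_size_nm`` (downward).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import InvalidParameterError

__all__ = ["Grid2D"]


@dataclass(frozen=True)
class Grid2D:
    """A 2-D pixel raster with a physical pixel pitch.

    Parameters
    ----------
    n_rows, n_cols : int
        Pixel counts, each at least 8.
    pixel_size_nm : float
        Physical size of one (square) pixel in nanometres.
    """

    n_rows: int
    n_cols: int
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise InvalidParameterError(
                f"grid must be at least 8x8, got {self.n_rows}x{self.n_cols}"
            )
        if not self.pixel_size_nm > 0:
            raise InvalidParameterError(
                f"pixel_size_nm must be positive, got {self.pixel_size_nm}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def origin(self) -> tuple[int, int]:
        """Index of the pixel at the physical origin."""
        return (self.n_rows // 2, self.n_cols // 2)

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical size (height, width) of the raster in nm."""
        return (self.n_rows * self.pixel_size_nm, self.n_cols * self.pixel_size_nm)

    @cached_property
    def x_nm(self) -> np.ndarray:
        """x coordinate (nm) of every pixel center, shape (n_rows, n_cols)."""
        j0 = self.n_cols // 2
        x = (np.arange(self.n_cols) - j0) * self.pixel_size_nm
        return np.broadcast_to(x[None, :], self.shape)

    @cached_property
    def y_nm(self) -> np.ndarray:
        """y coordinate (nm) of every pixel center, shape (n_rows, n_cols)."""
        i0 = self.n_rows // 2
        y = (np.arange(self.n_rows) - i0) * self.pixel_size_nm
        return np.broadcast_to(y[:, None], self.shape)

    @cached_property
    def r_nm(self) -> np.ndarray:
        """Radial distance (nm) from the physical origin."""
        return np.hypot(self.x_nm, self.y_nm)

    def contains_nm(self, x_nm: float, y_nm: float, margin_nm: float = 0.0) -> bool:
        """Whether physical point (x, y) lies inside the raster with a margin."""
        i0, j0 = self.origin
        x_min = (-j0) * self.pixel_size_nm + margin_nm
        x_max = (self.n_cols - 1 - j0) * self.pixel_size_nm - margin_nm
        y_min = (-i0) * self.pixel_size_nm + margin_nm
        y_max = (self.n_rows - 1 - i0) * self.pixel_size_nm - margin_nm
        return (x_min <= x_nm <= x_max) and (y_min <= y_nm <= y_max)
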