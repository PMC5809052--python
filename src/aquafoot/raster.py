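"""Minimal single-band raster container and TIFF I/O for scene stacks.

Scenes are gridded snapshots of land-surface temperature (K) and red/NIR
surface reflectance at one acquisition date. Grids are float32 numpy arrays
with a sentinel nodata value (-9999) and a simple north-up affine transform
(origin + square pixel size in metres). Synthetic scenes are CRS-agnostic;
when real grids are combined their transforms must match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["NODATA", "GridTransform", "SceneRaster", "write_band", "read_band"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid: world x/y of the upper-left corner and pixel size (m)."""

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 30.0

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin - (row + 0.5) * self.pixel_size
        return x, y


@dataclass
class SceneRaster:
    """One acquisition: LST plus red/NIR reflectance on a common grid."""

    scene_id: str
    date: Date
    lst_k: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    transform: GridTransform = GridTransform()

    def __post_init__(self) -> None:
        shapes = {self.lst_k.shape, self.red.shape, self.nir.shape}
        if len(shapes) != 1:
            raise ValueError("LST, red and NIR grids must share one shape")
        valid = self.valid_mask
        if valid.any():
            lst = self.lst_k[valid]
            if lst.min() < 250.0 or lst.max() > 350.0:
                raise ValueError("valid LST must lie within [250, 350] K")
            for name, band in (("red", self.red), ("nir", self.nir)):
                b = band[valid]
                if b.min() < 0.0 or b.max() > 1.0:
                    raise ValueError(f"valid {name} reflectance must lie within [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lst_k.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return (self.lst_k != NODATA) & (self.red != NODATA) & (self.nir != NODATA)


def write_band(path: str | Path, grid: np.ndarray) -> None:
    """Write a single-band float32 TIFF with nodata -9999."""
    tifffile.imwrite(str(path), np.asarray(grid, dtype=np.float32))


def read_band(path: str | Path) -> np.ndarray:
    grid = tifffile.imread(str(path))
    if grid.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {grid.shape}")
    return grid.astype(np.float32)
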