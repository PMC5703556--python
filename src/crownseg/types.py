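"""Shared domain containers for scenes, height grids and ground truth.

Coordinate convention: pixel (row, col), 0-based, row-major; map coordinates
are metres with the origin at the raster's top-left corner, x increasing with
columns and y decreasing with rows (north-up). The centre of pixel
``(row, col)`` lies at ``(origin_x + (col + 0.5) * px, origin_y - (row + 0.5) * px)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Transform",
    "SceneRaster",
    "HeightGrids",
    "GroundTruthTree",
    "NODATA_DEFAULT",
]

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class Transform:
    """Affine north-up geotransform: top-left origin plus square pixel size."""

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size}")

    def pixel_center(self, row, col):
        """Map coordinates of pixel centres (vectorised)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def close_to(self, other: "Transform", tol: float = 1e-6) -> bool:
        return (
            abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class SceneRaster:
    """Three aligned spectral bands (blue, green, red-edge) of a UAV orthomosaic.

    Band values are non-negative digital numbers or reflectances; the band
    ratios downstream are scale-free. ``nodata`` marks invalid pixels in any
    band; a pixel invalid in one band is treated as invalid everywhere.
    """

    blue: np.ndarray
    green: np.ndarray
    rededge: np.ndarray
    transform: Transform
    crs_tag: str = "local"
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        shapes = {self.blue.shape, self.green.shape, self.rededge.shape}
        if len(shapes) != 1:
            raise ValueError(f"band shapes differ: {shapes}")
        if self.blue.ndim != 2:
            raise ValueError("bands must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    def valid_mask(self) -> np.ndarray:
        """True where all three bands carry data."""
        m = np.ones(self.shape, dtype=bool)
        for band in (self.blue, self.green, self.rededge):
            m &= band != self.nodata
            m &= np.isfinite(band)
        return m

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.blue, self.green, self.rededge


@dataclass
class HeightGrids:
    """DEM (bare earth), DSM (top of canopy) and derived CHM, metres.

    Must share shape and transform with the companion :class:`SceneRaster`.
    ``chm`` may be ``None`` until :func:`crownseg.indices.compute_chm` fills it.
    """

    dem: np.ndarray
    dsm: np.ndarray
    chm: Optional[np.ndarray] = None
    transform: Optional[Transform] = None
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        if self.dem.shape != self.dsm.shape:
            raise ValueError(f"DEM shape {self.dem.shape} != DSM shape {self.dsm.shape}")
        if self.chm is not None and self.chm.shape != self.dem.shape:
            raise ValueError("CHM shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dem.shape

    def valid_mask(self) -> np.ndarray:
        m = (self.dem != self.nodata) & (self.dsm != self.nodata)
        m &= np.isfinite(self.dem) & np.isfinite(self.dsm)
        return m


SPECIES = ("sapote", "algarrobo", "overo", "other")


@dataclass
class GroundTruthTree:
    """One field-surveyed tree or shrub patch.

    ``health_grade`` follows the field convention for Algarrobo only:
    1 healthy, 2 infected, 3 dead. ``crown_spread_m2`` is the surveyed average
    crown spread; trees under 4 m2 are excluded from reference counts.
    """

    id: int
    species: str
    crown_spread_m2: float
    centroid: tuple[float, float]
    plot_id: Optional[int] = None
    health_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if (self.species == "algarrobo") != (self.health_grade is not None):
            raise ValueError("health_grade must be present iff species is algarrobo")
        if self.health_grade is not None and self.health_grade not in (1, 2, 3):
            raise ValueError(f"health_grade must be 1, 2 or 3, got {self.health_grade}")
        if not self.crown_spread_m2 > 0:
            raise ValueError("crown_spread_m2 must be > 0")
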