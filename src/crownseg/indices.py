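"""Band-ratio vegetation indices and the canopy height model.

Two normalised-difference ratios drive the whole workflow:

* ``GV`` (green vegetation, called GDVI in the rule set):
  ``(RE - G) / (RE + G)`` — high for photosynthetic canopies because
  reflectance rises sharply across the red edge.
* ``NPV`` (non-photosynthetic vegetation): ``(B - G) / (B + G)`` — leafless
  grey canopies and dead wood reflect relatively more blue than green.

Both are unit-free, so they work identically on raw digital numbers and on
reflectance. The CHM is simply ``max(DSM - DEM, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import HeightGrids, SceneRaster, NODATA_DEFAULT

__all__ = ["IndexGrid", "compute_gv", "compute_npv", "compute_chm"]


@dataclass
class IndexGrid:
    """A normalised-difference index in [-1, 1] with an explicit nodata mask."""

    values: np.ndarray
    kind: str  # "GV" or "NPV"
    valid: np.ndarray  # bool mask, True where the index is defined

    def __post_init__(self) -> None:
        if self.kind not in ("GV", "NPV"):
            raise ValueError(f"kind must be 'GV' or 'NPV', got {self.kind!r}")
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")

    @property
    def shape(self):
        return self.values.shape

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = fill
        return out


def _normalised_difference(a: np.ndarray, b: np.ndarray, valid: np.ndarray, kind: str) -> IndexGrid:
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    denom = a + b
    ok = valid & (denom != 0)
    values = np.zeros(a.shape, dtype=np.float64)
    np.divide(a - b, denom, out=values, where=ok)
    values[~ok] = 0.0
    return IndexGrid(values=values, kind=kind, valid=ok)


def compute_gv(scene: SceneRaster) -> IndexGrid:
    """GV = (RE - Green) / (RE + Green); degenerate pixels become nodata."""
    return _normalised_difference(scene.rededge, scene.green, scene.valid_mask(), "GV")


def compute_npv(scene: SceneRaster) -> IndexGrid:
    """NPV = (Blue - Green) / (Blue + Green); degenerate pixels become nodata."""
    return _normalised_difference(scene.blue, scene.green, scene.valid_mask(), "NPV")


def compute_chm(heights: HeightGrids) -> HeightGrids:
    """Fill ``heights.chm`` with max(DSM - DEM, 0); nodata propagates.

    Photogrammetric DSMs can dip below the DEM over bare ground; negative
    differences are clamped to zero. Idempotent.
    """
    valid = heights.valid_mask()
    chm = np.where(valid, np.maximum(heights.dsm - heights.dem, 0.0), heights.nodata)
    return HeightGrids(
        dem=heights.dem,
        dsm=heights.dsm,
        chm=chm,
        transform=heights.transform,
        nodata=heights.nodata,
    )
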