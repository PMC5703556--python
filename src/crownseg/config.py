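"""Rule-set configuration: every threshold of the two-level OBIA workflow.

Defaults reproduce the published processing-parameter table of the dry-forest
UAV survey this package operationalises: index thresholds for the vegetation
mask, the shape/extent tests that separate isolated crowns from tree clusters,
local-extrema search ranges for seed finding, and the species rule set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["RuleConfig", "load_config"]


@dataclass
class RuleConfig:
    # Level 1 — vegetation masking and isolated/cluster split
    npv_threshold: float = 0.053        # NPV > t  -> non-photosynthetic vegetation
    gdvi_threshold: float = 0.03        # GV (GDVI) > t -> green vegetation
    roundness_max: float = 0.9          # deviation-from-circle; smaller is rounder
    cluster_area_max_px: int = 30000    # larger objects are tree clusters
    mmu_m2: float = 4.0                 # minimum mapping unit

    # Multiresolution segmentation (scale/shape/compactness are not published;
    # eCognition-style starting values, fully exposed here)
    seg_scale: float = 20.0
    seg_shape: float = 0.1
    seg_compactness: float = 0.5
    weight_blue: float = 1.0
    weight_green: float = 1.0
    weight_rededge: float = 1.0
    weight_chm: float = 1.0

    # Level 2 — seed finding and contextual refinement
    seed_search_range_npv_px: int = 20  # window half-width, NPV maxima (dead/deciduous)
    seed_search_range_gv_px: int = 50   # window half-width, CHM maxima (green)
    seed_smoothing_sigma_px: float = 2.0  # Gaussian pre-smoothing of the guiding grid (0 = off)
    relative_border_merge_min: float = 0.5

    # Species rules
    sapote_gdvi_min: float = 0.08       # green crowns: GV >= t -> Sapote, else alive Algarrobo
    dead_area_min_px: int = 10000       # NPV crowns: area/height split dead Algarrobo vs Overo
    chm_bush_max_m: float = 0.4
    chm_statistic: str = "max"          # object CHM statistic the 0.4 m rule tests

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "chm_statistic":
                if v not in ("max", "mean"):
                    raise ValueError(f"chm_statistic must be 'max' or 'mean', got {v!r}")
                continue
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"{f.name} must be numeric, got {v!r}")
            if not abs(v) < float("inf"):
                raise ValueError(f"{f.name} must be finite")
        for name in ("cluster_area_max_px", "mmu_m2", "dead_area_min_px", "seg_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("seed_search_range_npv_px", "seed_search_range_gv_px"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seed_smoothing_sigma_px < 0:
            raise ValueError("seed_smoothing_sigma_px must be >= 0")
        if not 0.0 <= self.seg_shape < 1.0:
            raise ValueError("seg_shape must be in [0, 1)")
        if not 0.0 <= self.seg_compactness <= 1.0:
            raise ValueError("seg_compactness must be in [0, 1]")
        w = (self.weight_blue, self.weight_green, self.weight_rededge, self.weight_chm)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("layer weights must be >= 0 and not all zero")

    @property
    def layer_weights(self) -> tuple[float, float, float, float]:
        return (self.weight_blue, self.weight_green, self.weight_rededge, self.weight_chm)

    def mmu_px(self, pixel_size: float) -> int:
        """Minimum mapping unit in pixels for a given ground resolution."""
        return max(1, int(round(self.mmu_m2 / pixel_size**2)))

    def replace(self, **kwargs) -> "RuleConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RuleConfig)}
_INT_FIELDS = {
    "cluster_area_max_px",
    "dead_area_min_px",
    "seed_search_range_npv_px",
    "seed_search_range_gv_px",
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RuleConfig:
    """Read a flat ``key: value`` YAML config; absent keys take the defaults.

    Parameters
    ----------
    path
        Config file; ``None`` yields the pure defaults.
    overrides
        Applied on top of the file, same validation.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat key: value mapping")
        values.update(loaded)
    if overrides:
        values.update(overrides)

    known = set(_FIELD_TYPES)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, v in values.items():
        if key == "chm_statistic":
            continue
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValueError(f"config key {key} must be numeric, got {v!r}")
        if key in _INT_FIELDS:
            values[key] = int(v)
    return RuleConfig(**values)
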