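"""Rule-based species classification of delineated crowns.

Four classes: Sapote (Colicodendron scabridum), alive and dead Algarrobo
(Prosopis pallida) and Overo (Cordia lutea). Green crowns split on the GV
(GDVI) mean — Sapote's large sclerophyllous leaves push the red edge up —
and non-photosynthetic crowns split on extent and height: a big tall leafless
crown is a dead Algarrobo, a small low patch is the Overo shrub. Overo is
mapped but excluded from tree counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RuleConfig
from .pipeline import CrownObject, GREEN, NPV

__all__ = ["CLASSES", "TREE_CLASSES", "ClassifiedMap", "classify_crown", "classify_all"]

logger = logging.getLogger("crownseg")

CLASSES = ("sapote", "overo", "algarrobo_alive", "algarrobo_dead")
TREE_CLASSES = ("sapote", "algarrobo_alive", "algarrobo_dead")


@dataclass
class ClassifiedMap:
    """Crowns with class labels plus per-class tallies."""

    crowns: list  # of CrownObject, each with .label set
    counts: dict = field(default_factory=dict)
    area_m2: dict = field(default_factory=dict)

    @property
    def tree_count(self) -> int:
        """Number of trees: Overo, a bush, is identified but not quantified."""
        return sum(self.counts.get(c, 0) for c in TREE_CLASSES)

    def counts_by_plot(self, plots: pd.DataFrame) -> pd.DataFrame:
        """Per-plot per-class crown counts by centroid-in-plot (half-open)."""
        out = pd.DataFrame(
            0,
            index=pd.Index(plots["plot_id"].astype(int), name="plot_id"),
            columns=list(CLASSES),
        )
        for c in self.crowns:
            x, y = c.centroid_map
            for p in plots.itertuples():
                if p.x0 <= x < p.x1 and p.y0 <= y < p.y1:
                    out.at[int(p.plot_id), c.label] += 1
                    break
        return out


def classify_crown(crown: CrownObject, cfg: RuleConfig | None = None) -> str:
    """Assign one crown to a class from its features.

    Green vegetation: GV >= ``sapote_gdvi_min`` -> sapote, else alive
    Algarrobo. Non-photosynthetic vegetation: area >= ``dead_area_min_px``
    and CHM above ``chm_bush_max_m`` -> dead Algarrobo; small and low ->
    Overo. The two unruled quadrants (small-and-tall, large-and-short) are
    resolved by the height test alone — tree versus bush is the biologically
    decisive distinction — with a logged warning.
    """
    cfg = cfg or RuleConfig()
    f = crown.features
    for key in ("mean_gv", "mean_npv", "max_chm", "mean_chm", "area_px"):
        if key not in f:
            raise ValueError(f"crown {crown.id}: missing feature {key}")
    if crown.vegetation_kind == GREEN:
        return "sapote" if f["mean_gv"] >= cfg.sapote_gdvi_min else "algarrobo_alive"
    if crown.vegetation_kind != NPV:
        raise ValueError(f"crown {crown.id}: unknown vegetation kind {crown.vegetation_kind!r}")
    chm_stat = f["max_chm"] if cfg.chm_statistic == "max" else f["mean_chm"]
    big = f["area_px"] >= cfg.dead_area_min_px
    tall = chm_stat > cfg.chm_bush_max_m
    if big and tall:
        return "algarrobo_dead"
    if not big and not tall:
        return "overo"
    logger.warning(
        "crown %s falls in an unruled quadrant (area_px=%d, chm=%.2f); "
        "resolved by the height test alone",
        crown.id, int(f["area_px"]), chm_stat,
    )
    return "algarrobo_dead" if tall else "overo"


def classify_all(crowns: list, cfg: RuleConfig | None = None) -> ClassifiedMap:
    """Classify every crown; pure per-crown function, order-independent."""
    cfg = cfg or RuleConfig()
    counts = {c: 0 for c in CLASSES}
    areas = {c: 0.0 for c in CLASSES}
    for crown in crowns:
        crown.label = classify_crown(crown, cfg)
        counts[crown.label] += 1
        areas[crown.label] += crown.area_m2
    return ClassifiedMap(crowns=list(crowns), counts=counts, area_m2=areas)
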