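"""Landscape summarisation: fishnet grids, zonal crown cover, densities.

The classified map is summarised over a regular grid of square cells
(default 50 m, i.e. 2500 m2): trees per class by crown-centroid-in-cell,
crown cover by clipping crown polygons to the cells, and Algarrobo mortality
as dead / (dead + alive) per cell. Area-wide densities use the detection-
rate-adjusted abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from .classify import CLASSES, TREE_CLASSES, ClassifiedMap

__all__ = ["make_fishnet", "summarize_cells", "density_summary"]


def make_fishnet(
    extent: tuple[float, float, float, float], cell_size_m: float = 50.0
) -> pd.DataFrame:
    """Axis-aligned square cells anchored at the extent's lower-left corner.

    ``extent`` is (x0, y0, x1, y1) in map coordinates. Partial edge cells are
    included and flagged. Cells are half-open (left/bottom edges inclusive)
    for point queries but their polygons tile the extent exactly.
    """
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError("extent must have positive width and height")
    nx = int(np.ceil((x1 - x0) / cell_size_m - 1e-12))
    ny = int(np.ceil((y1 - y0) / cell_size_m - 1e-12))
    cells = []
    cid = 0
    for iy in range(ny):
        for ix in range(nx):
            cx0 = x0 + ix * cell_size_m
            cy0 = y0 + iy * cell_size_m
            cx1 = min(cx0 + cell_size_m, x1)
            cy1 = min(cy0 + cell_size_m, y1)
            cells.append(
                {
                    "cell_id": cid,
                    "ix": ix,
                    "iy": iy,
                    "x0": cx0,
                    "y0": cy0,
                    "x1": cx1,
                    "y1": cy1,
                    "partial": (cx1 - cx0 < cell_size_m - 1e-12)
                    or (cy1 - cy0 < cell_size_m - 1e-12),
                    "geometry": box(cx0, cy0, cx1, cy1),
                }
            )
            cid += 1
    return pd.DataFrame(cells).set_index("cell_id")


def summarize_cells(classified: ClassifiedMap, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell class counts, crown cover and Algarrobo mortality.

    Counts assign each crown to the cell containing its centroid (half-open
    cells, left/bottom inclusive); crown cover clips crown polygons to each
    cell, so summed cover over all cells conserves total crown area; the
    percentage of dead Algarrobo is NaN (undefined) where a cell holds no
    Algarrobo at all.
    """
    out = cells.copy()
    for c in CLASSES:
        out[f"n_{c}"] = 0
    out["n_trees"] = 0
    out["crown_cover_m2"] = 0.0

    x0 = cells["x0"].min()
    y0 = cells["y0"].min()
    # nominal cell size: the largest cell edge (edge cells may be partial)
    step = max((cells["x1"] - cells["x0"]).max(), (cells["y1"] - cells["y0"]).max())
    by_pos = {(int(r.ix), int(r.iy)): idx for idx, r in cells.iterrows()}

    for crown in classified.crowns:
        cx, cy = crown.centroid_map
        ix = int(np.floor((cx - x0) / step))
        iy = int(np.floor((cy - y0) / step))
        idx = by_pos.get((ix, iy))
        if idx is not None:
            out.at[idx, f"n_{crown.label}"] += 1
            if crown.label in TREE_CLASSES:
                out.at[idx, "n_trees"] += 1
        if crown.polygon is None:
            continue
        minx, miny, maxx, maxy = crown.polygon.bounds
        for jx in range(int(np.floor((minx - x0) / step)), int(np.floor((maxx - x0) / step)) + 1):
            for jy in range(int(np.floor((miny - y0) / step)), int(np.floor((maxy - y0) / step)) + 1):
                jdx = by_pos.get((jx, jy))
                if jdx is None:
                    continue
                inter = crown.polygon.intersection(cells.at[jdx, "geometry"])
                if not inter.is_empty:
                    out.at[jdx, "crown_cover_m2"] += inter.area

    dead = out["n_algarrobo_dead"].astype(float)
    alive = out["n_algarrobo_alive"].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * dead / (dead + alive)
    pct[(dead + alive) == 0] = np.nan
    out["pct_dead_algarrobo"] = pct
    return out


def density_summary(
    adjusted_counts: dict, area_ha: float, raw_counts: dict | None = None
) -> pd.DataFrame:
    """Area-wide abundance table: counts, trees/ha, species shares, mortality.

    ``adjusted_counts`` maps the three tree classes to detection-adjusted
    totals. Percentages: species share of all trees (Algarrobo pooled over
    alive + dead), and percent dead among Algarrobo. Percentages are rounded
    to integers for reporting, densities to 0.1 trees/ha; full precision is
    retained in the ``*_exact`` columns.
    """
    if not area_ha > 0:
        raise ValueError("area_ha must be positive")
    total = sum(adjusted_counts[c] for c in TREE_CLASSES)
    alg = adjusted_counts["algarrobo_alive"] + adjusted_counts["algarrobo_dead"]
    rows = {}
    for c in TREE_CLASSES:
        n = adjusted_counts[c]
        share = 100.0 * (alg if c.startswith("algarrobo") else n) / total
        rows[c] = {
            "raw": (raw_counts or {}).get(c, np.nan),
            "adjusted": n,
            "per_ha": round(n / area_ha, 1),
            "per_ha_exact": n / area_ha,
            "pct_trees": round(share),
            "pct_trees_exact": share,
        }
    dead_pct = 100.0 * adjusted_counts["algarrobo_dead"] / alg if alg else np.nan
    rows["algarrobo_dead"]["pct_dead"] = round(dead_pct)
    rows["algarrobo_dead"]["pct_dead_exact"] = dead_pct
    rows["total"] = {
        "raw": sum((raw_counts or {}).get(c, 0) for c in TREE_CLASSES) if raw_counts else np.nan,
        "adjusted": total,
        "per_ha": round(total / area_ha, 1),
        "per_ha_exact": total / area_ha,
    }
    out = pd.DataFrame(rows).T
    out.index.name = "class"
    return out
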