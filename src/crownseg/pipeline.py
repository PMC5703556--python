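"""Two-level crown delineation.

Level 1 turns segmentation objects into vegetation objects (index
thresholding, merging, hole absorption, minimum-mapping-unit removal) and
splits them into isolated crowns versus tree clusters by shape and extent.
Level 2 de-clusters: seed pixels are local maxima — of NPV for leafless/dead
vegetation (photogrammetric CHMs fail over sparse branches) and of the CHM
for green vegetation — and a best-first region growing assigns every cluster
pixel to the seed whose value it matches most closely. A final contextual
pass merges crown fragments of differing vegetation kind that share most of
their border, the signature of an infested tree split into dead and leafy
parts.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.validation import make_valid
from skimage.measure import find_contours

from .config import RuleConfig
from .indices import IndexGrid, compute_chm, compute_gv, compute_npv
from .segmentation import SegmentMap, compute_features, roundness_of_mask, segment
from .types import HeightGrids, SceneRaster, Transform

__all__ = [
    "CrownObject",
    "mask_vegetation",
    "split_isolated_vs_cluster",
    "find_seeds",
    "grow_crowns",
    "refine_crowns",
    "delineate_crowns",
]

logger = logging.getLogger("crownseg")

GREEN = "green"
NPV = "npv"
BACKGROUND = "background"


@dataclass
class CrownObject:
    """One delineated tree crown."""

    id: int
    rows: np.ndarray  # pixel footprint, row indices
    cols: np.ndarray
    vegetation_kind: str  # "green" | "npv"
    provenance: str  # "isolated" | "declustered"
    features: pd.Series
    transform: Transform
    label: Optional[str] = None  # species class, set by the classifier
    polygon: Optional[Polygon] = None

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def area_m2(self) -> float:
        return self.area_px * self.transform.pixel_size**2

    @property
    def centroid_map(self) -> tuple[float, float]:
        x, y = self.transform.pixel_center(self.rows.mean(), self.cols.mean())
        return float(x), float(y)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def crown_features(rows, cols, grids: dict, transform: Transform) -> pd.Series:
    """Summary features of a pixel footprint from the stashed source grids."""
    scene = grids["scene"]
    heights = grids["heights"]
    gv = grids["gv"]
    npv = grids["npv"]
    px = transform.pixel_size
    n = rows.size
    feats = {"area_px": n, "area_m2": n * px * px}
    for name, grid in (
        ("blue", scene.blue),
        ("green", scene.green),
        ("rededge", scene.rededge),
        ("chm", heights.chm),
    ):
        v = grid[rows, cols].astype(np.float64)
        feats[f"mean_{name}"] = v.mean()
        feats[f"sd_{name}"] = v.std()
    feats["max_chm"] = float(heights.chm[rows, cols].max())
    for key, ig in (("mean_gv", gv), ("mean_npv", npv)):
        vals = ig.values[rows, cols]
        ok = ig.valid[rows, cols]
        feats[key] = float(vals[ok].mean()) if ok.any() else np.nan
    feats["centroid_row"] = float(rows.mean())
    feats["centroid_col"] = float(cols.mean())
    return pd.Series(feats)


# ---------------------------------------------------------------------------
# Level 1


def _bulk_relabel(seg: SegmentMap, mapping: dict[int, int]) -> None:
    """Apply label -> label mapping on the grid (identity for absent keys)."""
    if not mapping:
        return
    k = int(seg.labels.max())
    lut = np.arange(k + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    # resolve chains (a->b, b->c)
    for _ in range(32):
        nxt = lut[lut]
        if np.array_equal(nxt, lut):
            break
        lut = nxt
    seg.labels = lut[seg.labels]


def _tag_objects(table: pd.DataFrame, cfg: RuleConfig) -> pd.Series:
    npv_veg = table["mean_npv"] > cfg.npv_threshold
    green_veg = ~npv_veg & (table["mean_gv"] > cfg.gdvi_threshold)
    tag = pd.Series(BACKGROUND, index=table.index)
    tag[npv_veg] = NPV
    tag[green_veg] = GREEN
    return tag


def _touches_border(labels: np.ndarray, lab: int) -> bool:
    return bool(
        (labels[0] == lab).any()
        or (labels[-1] == lab).any()
        or (labels[:, 0] == lab).any()
        or (labels[:, -1] == lab).any()
    )


def mask_vegetation(seg: SegmentMap, cfg: RuleConfig) -> SegmentMap:
    """Tag objects green / npv / background and consolidate vegetation.

    Thresholds: NPV above ``npv_threshold`` wins over the green test. Adjacent
    same-tag vegetation objects are merged; background objects fully enclosed
    by a single vegetation object are absorbed into it; vegetation smaller
    than the minimum mapping unit is dropped back to background.
    """
    if seg.table is None:
        raise ValueError("compute_features must run before mask_vegetation")
    grids = seg.grids
    tag = _tag_objects(seg.table, cfg)

    # merge adjacent vegetation of the same kind (union-find over the
    # object adjacency graph)
    parent = {lab: lab for lab in seg.table.index}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lab in seg.table.index:
        if tag[lab] == BACKGROUND:
            continue
        for nb in seg.neighbors.get(lab, {}):
            if nb in tag.index and tag[nb] == tag[lab]:
                ra, rb = find(lab), find(nb)
                if ra != rb:
                    lo, hi = sorted((ra, rb))
                    parent[hi] = lo
    mapping = {lab: find(lab) for lab in parent if find(lab) != lab}
    _bulk_relabel(seg, mapping)
    compute_features(seg, grids["scene"], grids["heights"], grids["gv"], grids["npv"])
    # retag on the merged objects: a group of same-tag parts keeps its tag
    # (the merged mean is a weighted mean of the parts' means)
    tag = _tag_objects(seg.table, cfg)

    # absorb background holes fully enclosed by one vegetation object
    absorb = {}
    for lab in seg.table.index:
        if tag[lab] != BACKGROUND:
            continue
        nbs = set(seg.neighbors.get(lab, {}))
        if len(nbs) == 1:
            (v,) = nbs
            if tag.get(v) in (GREEN, NPV) and not _touches_border(seg.labels, lab):
                absorb[lab] = v
    if absorb:
        _bulk_relabel(seg, absorb)
        compute_features(seg, grids["scene"], grids["heights"], grids["gv"], grids["npv"])
        tag = tag.drop(index=list(absorb)).reindex(seg.table.index, fill_value=BACKGROUND)

    # minimum mapping unit
    small = (seg.table["area_m2"] < cfg.mmu_m2) & tag.isin([GREEN, NPV])
    tag[small] = BACKGROUND

    seg.table["tag"] = tag
    return seg


def split_isolated_vs_cluster(
    seg: SegmentMap, cfg: RuleConfig
) -> tuple[list[CrownObject], list[dict]]:
    """Vegetation objects become isolated crowns or clusters (extent + shape).

    Isolated iff roundness < ``roundness_max`` and area < ``cluster_area_max_px``.
    Clusters carry their footprint and vegetation kind to Level 2.
    """
    if seg.table is None or "tag" not in seg.table:
        raise ValueError("mask_vegetation must run first")
    isolated: list[CrownObject] = []
    clusters: list[dict] = []
    for lab, row in seg.table.iterrows():
        if row["tag"] not in (GREEN, NPV):
            continue
        rows, cols = np.nonzero(seg.labels == lab)
        if row["roundness"] < cfg.roundness_max and row["area_px"] < cfg.cluster_area_max_px:
            isolated.append(
                CrownObject(
                    id=-1,
                    rows=rows,
                    cols=cols,
                    vegetation_kind=row["tag"],
                    provenance="isolated",
                    features=crown_features(rows, cols, seg.grids, seg.transform),
                    transform=seg.transform,
                )
            )
        else:
            clusters.append({"label": int(lab), "kind": row["tag"], "rows": rows, "cols": cols})
    return isolated, clusters


# ---------------------------------------------------------------------------
# Level 2


def cluster_guide(
    cluster_mask: np.ndarray, mode: str, cfg: RuleConfig, *, npv: IndexGrid | None = None,
    chm: np.ndarray | None = None, chm_valid: np.ndarray | None = None,
) -> np.ndarray:
    """The guiding surface for seeding/growing: NPV (npv mode) or CHM (green).

    Smoothed by a Gaussian of ``seed_smoothing_sigma_px`` via normalised
    convolution restricted to the cluster (per-pixel sensor noise otherwise
    litters the local-extrema search with spurious maxima); pixels outside
    the cluster — and, in green mode, CHM-nodata pixels — are ``-inf``.
    """
    if mode == NPV:
        if npv is None:
            raise ValueError("npv grid required in npv mode")
        ok = cluster_mask & npv.valid
        values = npv.values
    elif mode == GREEN:
        if chm is None:
            raise ValueError("chm grid required in green mode")
        ok = cluster_mask if chm_valid is None else (cluster_mask & chm_valid)
        values = chm
    else:
        raise ValueError(f"unknown seed mode {mode!r}")
    sigma = float(cfg.seed_smoothing_sigma_px)
    if sigma > 0:
        num = ndimage.gaussian_filter(np.where(ok, values, 0.0), sigma)
        den = ndimage.gaussian_filter(ok.astype(np.float64), sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num / den
    return np.where(ok, values, -np.inf)


def find_seeds(
    cluster_mask: np.ndarray, mode: str, cfg: RuleConfig, *, npv: IndexGrid | None = None,
    chm: np.ndarray | None = None, chm_valid: np.ndarray | None = None,
    guide: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Seed pixels: strict local maxima of the guiding grid within the cluster.

    ``npv`` mode scans the (smoothed) NPV grid in a square window of
    half-width ``seed_search_range_npv_px``; ``green`` mode scans the CHM
    with half-width ``seed_search_range_gv_px`` (CHM-nodata pixels cannot
    seed). Plateau ties go to the lexicographically lowest (row, col). A
    precomputed ``guide`` (from :func:`cluster_guide`) skips the rebuild.
    """
    if not cluster_mask.any():
        raise ValueError("empty cluster")
    if guide is None:
        guide = cluster_guide(cluster_mask, mode, cfg, npv=npv, chm=chm, chm_valid=chm_valid)
    half = int(
        cfg.seed_search_range_npv_px if mode == NPV else cfg.seed_search_range_gv_px
    )
    size = 2 * half + 1
    local_max = ndimage.maximum_filter(guide, size=size, mode="constant", cval=-np.inf)
    cand = np.argwhere((guide == local_max) & np.isfinite(guide) & cluster_mask)
    seeds = []
    H, W = guide.shape
    for r, c in cand:
        v = guide[r, c]
        r0, r1 = max(0, r - half), min(H, r + half + 1)
        c0, c1 = max(0, c - half), min(W, c + half + 1)
        win = guide[r0:r1, c0:c1]
        if (win > v).any():
            continue
        ties = np.argwhere(win == v)
        ties_abs = ties + (r0, c0)
        first = min((int(tr), int(tc)) for tr, tc in ties_abs)
        if first == (int(r), int(c)):
            seeds.append((int(r), int(c)))
    return sorted(seeds)


def grow_crowns(
    cluster: dict,
    seeds: list[tuple[int, int]],
    guide: np.ndarray,
    cfg: RuleConfig,
    grids: dict,
    transform: Transform,
) -> list[CrownObject]:
    """Partition the cluster among seeds by best-first region growing.

    The unassigned cluster pixel 4-adjacent to a region whose guiding value
    differs least from that region's seed value is assigned next; ties break
    on (row, col, region). Sub-MMU regions are merged into the neighbouring
    region with the longest shared border. With no seeds the whole cluster is
    returned as one crown (logged).
    """
    rows, cols = cluster["rows"], cluster["cols"]
    H, W = guide.shape
    in_cluster = np.zeros((H, W), dtype=bool)
    in_cluster[rows, cols] = True

    if not seeds:
        logger.warning("cluster %s has no seeds; returned as a single crown", cluster.get("label"))
        assign = np.full((H, W), -1, dtype=np.int32)
        assign[in_cluster] = 0
        regions = [np.nonzero(assign == 0)]
    else:
        seed_vals = [float(guide[r, c]) for r, c in seeds]
        assign = np.full((H, W), -1, dtype=np.int32)
        heap = []
        for i, (r, c) in enumerate(seeds):
            heapq.heappush(heap, (0.0, r, c, i))
        while heap:
            _, r, c, reg = heapq.heappop(heap)
            if assign[r, c] != -1:
                continue
            assign[r, c] = reg
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < H and 0 <= nc < W and in_cluster[nr, nc] and assign[nr, nc] == -1:
                    diff = abs(float(guide[nr, nc]) - seed_vals[reg])
                    heapq.heappush(heap, (diff, nr, nc, reg))
        regions = [np.nonzero(assign == i) for i in range(len(seeds))]

    # merge sub-MMU regions into the neighbour with the longest shared border
    mmu_px = cfg.mmu_px(transform.pixel_size)
    alive = {i for i, reg in enumerate(regions) if reg[0].size > 0}

    def border_len(i, j):
        mi = assign == i
        mj = assign == j
        n = 0
        for ax, sh in ((0, 1), (1, 1)):
            a = np.roll(mi, sh, axis=ax)
            n += int((a & mj).sum())
            b = np.roll(mj, sh, axis=ax)
            n += int((b & mi).sum())
        return n

    changed = True
    while changed:
        changed = False
        small = sorted(
            (i for i in alive if (assign == i).sum() < mmu_px and len(alive) > 1),
            key=lambda i: int((assign == i).sum()),
        )
        for i in small:
            best, best_len = None, 0
            for j in alive:
                if j == i:
                    continue
                bl = border_len(i, j)
                if bl > best_len:
                    best, best_len = j, bl
            if best is not None:
                assign[assign == i] = best
                alive.discard(i)
                changed = True
                break

    crowns = []
    for i in sorted(alive):
        rr, cc = np.nonzero(assign == i)
        crowns.append(
            CrownObject(
                id=-1,
                rows=rr,
                cols=cc,
                vegetation_kind=cluster["kind"],
                provenance="declustered",
                features=crown_features(rr, cc, grids, transform),
                transform=transform,
            )
        )
    return crowns


# ---------------------------------------------------------------------------
# contextual refinement


def _crown_label_grid(crowns: list[CrownObject], shape) -> np.ndarray:
    grid = np.full(shape, -1, dtype=np.int32)
    for i, c in enumerate(crowns):
        grid[c.rows, c.cols] = i
    return grid


def _crown_borders(grid: np.ndarray) -> tuple[dict, dict]:
    """Pairwise shared borders and total border length per crown index."""
    shared: dict = {}
    total: dict = {}
    padded = np.pad(grid, 1, constant_values=-1)
    for sh in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rolled = np.roll(padded, sh, axis=(0, 1))
        here = padded
        edge = (here >= 0) & (here != rolled)
        labs, counts = np.unique(here[edge], return_counts=True)
        for l, n in zip(labs, counts):
            total[int(l)] = total.get(int(l), 0) + int(n)
        both = edge & (rolled >= 0)
        a = here[both]
        b = rolled[both]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        for pair in zip(lo.tolist(), hi.tolist()):
            shared[pair] = shared.get(pair, 0) + 1
    # each undirected pair counted twice (once from each side)
    shared = {k: v // 2 for k, v in shared.items()}
    return shared, total


def refine_crowns(
    crowns: list[CrownObject], cfg: RuleConfig, grids: dict, shape: tuple[int, int]
) -> list[CrownObject]:
    """Merge mixed-kind crown fragments that share most of their border.

    A crown whose relative border to one neighbouring crown of the *other*
    vegetation kind exceeds ``relative_border_merge_min`` is absorbed into
    that neighbour (dead branches next to partially defoliated branches of
    the same infested tree). Single pass, largest relative border first.
    """
    if len(crowns) < 2:
        return crowns
    grid = _crown_label_grid(crowns, shape)
    shared, total = _crown_borders(grid)
    candidates = []
    for (i, j), bl in shared.items():
        if crowns[i].vegetation_kind == crowns[j].vegetation_kind:
            continue
        for src, dst in ((i, j), (j, i)):
            rel = bl / total[src] if total.get(src) else 0.0
            if rel > cfg.relative_border_merge_min:
                candidates.append((rel, src, dst))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    dead: set[int] = set()
    merged_into: dict[int, int] = {}
    for rel, src, dst in candidates:
        if src in dead or dst in dead:
            continue
        merged_into[src] = dst
        dead.add(src)
    if not merged_into:
        return crowns
    out = []
    groups: dict[int, list[int]] = {}
    for i in range(len(crowns)):
        if i in dead:
            continue
        groups[i] = [i]
    for src, dst in merged_into.items():
        while dst in merged_into:
            dst = merged_into[dst]
        groups.setdefault(dst, [dst]).append(src)
    for dst, members in groups.items():
        if len(members) == 1:
            out.append(crowns[dst])
            continue
        rr = np.concatenate([crowns[m].rows for m in members])
        cc = np.concatenate([crowns[m].cols for m in members])
        base = crowns[dst]
        out.append(
            CrownObject(
                id=-1,
                rows=rr,
                cols=cc,
                vegetation_kind=base.vegetation_kind,
                provenance=base.provenance,
                features=crown_features(rr, cc, grids, base.transform),
                transform=base.transform,
            )
        )
    return out


# ---------------------------------------------------------------------------
# polygons and the full Level 1 + Level 2 driver


def crown_polygon(crown: CrownObject) -> Polygon:
    """Map-coordinate polygon of the footprint (marching-squares outline)."""
    r0, r1 = crown.rows.min(), crown.rows.max()
    c0, c1 = crown.cols.min(), crown.cols.max()
    sub = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=float)
    sub[crown.rows - r0 + 1, crown.cols - c0 + 1] = 1.0
    contours = find_contours(sub, 0.5)
    tf = crown.transform

    def to_map(contour):
        rr = contour[:, 0] + r0 - 1
        cc = contour[:, 1] + c0 - 1
        x = tf.origin_x + (cc + 0.5) * tf.pixel_size
        y = tf.origin_y - (rr + 0.5) * tf.pixel_size
        return np.column_stack([x, y])

    rings = sorted(contours, key=lambda c: -abs(_shoelace(c)))
    poly = Polygon(to_map(rings[0]), [to_map(r) for r in rings[1:]])
    if not poly.is_valid:
        poly = make_valid(poly)
    return poly


def _shoelace(contour: np.ndarray) -> float:
    x = contour[:, 1]
    y = contour[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def delineate_crowns(
    scene: SceneRaster,
    heights: HeightGrids,
    cfg: RuleConfig | None = None,
    *,
    seg: SegmentMap | None = None,
    return_intermediate: bool = False,
):
    """Run Levels 1 and 2 end to end; returns the list of crowns.

    With ``return_intermediate`` also returns a dict holding the index grids,
    the vegetation-tagged segmentation and the cluster list.
    """
    cfg = cfg or RuleConfig()
    heights = compute_chm(heights)
    gv = compute_gv(scene)
    npv = compute_npv(scene)
    if seg is None:
        seg = segment(scene, heights, cfg)
    compute_features(seg, scene, heights, gv, npv)
    mask_vegetation(seg, cfg)
    isolated, clusters = split_isolated_vs_cluster(seg, cfg)
    grids = seg.grids
    chm_valid = heights.valid_mask()
    crowns = list(isolated)
    for cl in clusters:
        cluster_mask = np.zeros(seg.labels.shape, dtype=bool)
        cluster_mask[cl["rows"], cl["cols"]] = True
        guide = cluster_guide(
            cluster_mask, cl["kind"], cfg, npv=npv, chm=heights.chm, chm_valid=chm_valid
        )
        seeds = find_seeds(cluster_mask, cl["kind"], cfg, guide=guide)
        crowns.extend(grow_crowns(cl, seeds, guide, cfg, grids, seg.transform))
    crowns = refine_crowns(crowns, cfg, grids, seg.labels.shape)
    # drop any crown that ended below the MMU (possible after refinement edge cases)
    mmu_px = cfg.mmu_px(seg.pixel_size)
    crowns = [c for c in crowns if c.area_px >= mmu_px]
    crowns.sort(key=lambda c: (c.features["centroid_row"], c.features["centroid_col"]))
    for i, c in enumerate(crowns, start=1):
        c.id = i
        c.polygon = crown_polygon(c)
    if return_intermediate:
        return crowns, {"seg": seg, "gv": gv, "npv": npv, "heights": heights, "clusters": clusters}
    return crowns
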