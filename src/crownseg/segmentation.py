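"""Multiresolution segmentation and per-object features.

The segmenter is a bottom-up pairwise region-merging algorithm in the
Baatz-Schäpe tradition used by OBIA software: starting from single pixels,
regions merge with the neighbour that minimises the increase in weighted
heterogeneity, where

* the colour term is ``sum_b w_b * (n_m * sigma_m,b - n_1 * sigma_1,b - n_2 * sigma_2,b)``
  over the four layers (blue, green, red-edge, CHM), and
* the shape term mixes compactness (``P / sqrt(n)``) and smoothness
  (``P / bounding-box perimeter``), weighted the same extensive way.

A merge is admissible while its cost stays below ``scale**2``. Merging follows
the local-mutual-best-fit strategy in synchronous rounds: each region
nominates its cheapest neighbour (ties broken toward the smaller region id,
regions identified by their smallest pixel id) and mutually nominating pairs
merge. Rounds repeat until no admissible merge remains, which makes the result
deterministic and independent of traversal order. Objects are 4-connected;
border lengths count shared pixel edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from skimage.measure import perimeter_crofton as _crofton_perimeter

from .config import RuleConfig
from .indices import IndexGrid, compute_chm
from .types import HeightGrids, SceneRaster, Transform

__all__ = ["SegmentMap", "segment", "compute_features", "merge_objects", "merge_cost"]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _find_root(parent, i):
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


@njit(cache=True)
def _find_many(parent, idxs, out):
    for k in range(idxs.size):
        out[k] = _find_root(parent, idxs[k])


@njit(cache=True)
def _pair_cost(
    u, v, bl, cnt, s, ss, perim, rmin, rmax, cmin, cmax, w, wshape, wcmp
):
    nu = cnt[u]
    nv = cnt[v]
    nm = nu + nv
    hcol = 0.0
    for b in range(4):
        if w[b] == 0.0:
            continue
        su = s[u, b] + s[v, b]
        ssu = ss[u, b] + ss[v, b]
        var_m = ssu / nm - (su / nm) ** 2
        sig_m = math.sqrt(var_m) if var_m > 0.0 else 0.0
        var_u = ss[u, b] / nu - (s[u, b] / nu) ** 2
        sig_u = math.sqrt(var_u) if var_u > 0.0 else 0.0
        var_v = ss[v, b] / nv - (s[v, b] / nv) ** 2
        sig_v = math.sqrt(var_v) if var_v > 0.0 else 0.0
        hcol += w[b] * (nm * sig_m - nu * sig_u - nv * sig_v)
    if wshape == 0.0:
        return hcol
    pm = perim[u] + perim[v] - 2.0 * bl
    rmn = min(rmin[u], rmin[v])
    rmx = max(rmax[u], rmax[v])
    cmn = min(cmin[u], cmin[v])
    cmx = max(cmax[u], cmax[v])
    bb_m = 2.0 * ((rmx - rmn + 1) + (cmx - cmn + 1))
    bb_u = 2.0 * ((rmax[u] - rmin[u] + 1) + (cmax[u] - cmin[u] + 1))
    bb_v = 2.0 * ((rmax[v] - rmin[v] + 1) + (cmax[v] - cmin[v] + 1))
    h_cmp = nm * pm / math.sqrt(nm) - (
        nu * perim[u] / math.sqrt(nu) + nv * perim[v] / math.sqrt(nv)
    )
    h_sm = nm * pm / bb_m - (nu * perim[u] / bb_u + nv * perim[v] / bb_v)
    hshape = wcmp * h_cmp + (1.0 - wcmp) * h_sm
    return (1.0 - wshape) * hcol + wshape * hshape


@njit(cache=True)
def _update_costs(
    eu, ev, eb, ecost, changed, cnt, s, ss, perim, rmin, rmax, cmin, cmax, w, wshape, wcmp
):
    for k in range(eu.size):
        u = eu[k]
        v = ev[k]
        if changed[u] or changed[v]:
            ecost[k] = _pair_cost(
                u, v, eb[k], cnt, s, ss, perim, rmin, rmax, cmin, cmax, w, wshape, wcmp
            )


@njit(cache=True)
def _best_pass(eu, ev, eb, ecost, prio, thresh, best_cost, best_nb, best_border):
    # ties in cost break on a fixed pseudo-random region priority (then id):
    # an id-ordered tie-break forms long one-directional nomination chains on
    # homogeneous areas, which stalls mutual-best merging
    for k in range(eu.size):
        f = ecost[k]
        if f >= thresh:
            continue
        u = eu[k]
        v = ev[k]
        bu = best_nb[u]
        if f < best_cost[u] or (
            f == best_cost[u] and (prio[v] < prio[bu] or (prio[v] == prio[bu] and v < bu))
        ):
            best_cost[u] = f
            best_nb[u] = v
            best_border[u] = eb[k]
        bv = best_nb[v]
        if f < best_cost[v] or (
            f == best_cost[v] and (prio[u] < prio[bv] or (prio[u] == prio[bv] and u < bv))
        ):
            best_cost[v] = f
            best_nb[v] = u
            best_border[v] = eb[k]


@njit(cache=True)
def _merge_pass(
    best_nb, best_border, parent, cnt, s, ss, perim, rmin, rmax, cmin, cmax, used
):
    merged = 0
    for r in range(parent.size):
        if parent[r] != r or used[r]:
            continue
        b = best_nb[r]
        if b >= parent.size:  # sentinel: no admissible neighbour
            continue
        if b <= r:  # pairs handled once, from the smaller region id
            continue
        if used[b] or best_nb[b] != r:
            continue
        # merge b into r; the smaller id survives
        parent[b] = r
        cnt[r] += cnt[b]
        for lb in range(4):
            s[r, lb] += s[b, lb]
            ss[r, lb] += ss[b, lb]
        perim[r] = perim[r] + perim[b] - 2.0 * best_border[r]
        rmin[r] = min(rmin[r], rmin[b])
        rmax[r] = max(rmax[r], rmax[b])
        cmin[r] = min(cmin[r], cmin[b])
        cmax[r] = max(cmax[r], cmax[b])
        used[r] = True
        used[b] = True
        merged += 1
    return merged


# ---------------------------------------------------------------------------


@dataclass
class SegmentMap:
    """Integer label partition of the valid pixels plus a per-object table.

    ``labels`` is int32, 0 marks nodata/unassigned, objects are numbered from
    1 in row-major order of their first pixel. ``table`` (filled by
    :func:`compute_features`) is indexed by label; ``neighbors`` maps each
    label to ``{neighbour_label: shared border length in pixel edges}``.
    """

    labels: np.ndarray
    transform: Transform
    table: Optional[pd.DataFrame] = None
    neighbors: Optional[dict] = None
    grids: dict = field(default_factory=dict, repr=False)  # stashed source grids

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def check_partition(self, valid: np.ndarray | None = None) -> None:
        """Assert labels partition the valid pixels into 4-connected objects."""
        if valid is not None:
            if not np.array_equal(self.labels > 0, valid):
                raise AssertionError("labels do not cover exactly the valid pixels")
        for lab in np.unique(self.labels):
            if lab == 0:
                continue
            _, ncomp = ndimage.label(self.labels == lab)
            if ncomp != 1:
                raise AssertionError(f"object {lab} is not 4-connected ({ncomp} components)")


def _layers(scene: SceneRaster, heights: HeightGrids) -> tuple[np.ndarray, np.ndarray]:
    if heights.chm is None:
        heights = compute_chm(heights)
    valid = scene.valid_mask() & heights.valid_mask()
    stack = np.stack(
        [
            scene.blue.astype(np.float64),
            scene.green.astype(np.float64),
            scene.rededge.astype(np.float64),
            heights.chm.astype(np.float64),
        ]
    )
    stack[:, ~valid] = 0.0
    return stack, valid


def merge_cost(
    stats_a: dict, stats_b: dict, border: float, weights, shape: float, compactness: float
) -> float:
    """Heterogeneity increase of merging two regions, from their summary stats.

    Each stats dict needs keys ``n``, ``sum`` (len-4), ``sumsq`` (len-4),
    ``perimeter``, ``bbox`` (rmin, rmax, cmin, cmax). Exposed so tests can
    brute-force the criterion independently of the merge engine.
    """
    cnt = np.array([stats_a["n"], stats_b["n"]], dtype=np.float64)
    s = np.array([stats_a["sum"], stats_b["sum"]], dtype=np.float64)
    ss = np.array([stats_a["sumsq"], stats_b["sumsq"]], dtype=np.float64)
    perim = np.array([stats_a["perimeter"], stats_b["perimeter"]], dtype=np.float64)
    ra = stats_a["bbox"]
    rb = stats_b["bbox"]
    rmin = np.array([ra[0], rb[0]], dtype=np.int64)
    rmax = np.array([ra[1], rb[1]], dtype=np.int64)
    cmin = np.array([ra[2], rb[2]], dtype=np.int64)
    cmax = np.array([ra[3], rb[3]], dtype=np.int64)
    return float(
        _pair_cost(
            0, 1, float(border), cnt, s, ss, perim, rmin, rmax, cmin, cmax,
            np.asarray(weights, dtype=np.float64), float(shape), float(compactness),
        )
    )


def segment(
    scene: SceneRaster,
    heights: HeightGrids,
    cfg: RuleConfig | None = None,
    *,
    weights=None,
    scale: float | None = None,
    shape: float | None = None,
    compactness: float | None = None,
) -> SegmentMap:
    """Segment the four-layer stack (B, G, RE, CHM) into image objects.

    Explicit keyword arguments override the values in ``cfg``.
    """
    cfg = cfg or RuleConfig()
    w = np.asarray(weights if weights is not None else cfg.layer_weights, dtype=np.float64)
    if w.shape != (4,) or np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be 4 non-negative values, not all zero")
    scale = float(scale if scale is not None else cfg.seg_scale)
    wshape = float(shape if shape is not None else cfg.seg_shape)
    wcmp = float(compactness if compactness is not None else cfg.seg_compactness)

    stack, valid = _layers(scene, heights)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid pixels to segment")

    idx = np.full(valid.shape, -1, dtype=np.int64)
    idx[valid] = np.arange(n, dtype=np.int64)

    # initial per-pixel regions
    vals = stack[:, valid].T.copy()  # (n, 4)
    cnt = np.ones(n, dtype=np.float64)
    s = vals.astype(np.float64)
    ss = vals.astype(np.float64) ** 2
    perim = np.full(n, 4.0, dtype=np.float64)
    rows, cols = np.nonzero(valid)
    rmin = rows.astype(np.int64).copy()
    rmax = rows.astype(np.int64).copy()
    cmin = cols.astype(np.int64).copy()
    cmax = cols.astype(np.int64).copy()
    parent = np.arange(n, dtype=np.int64)

    # 4-adjacency edge list over valid pixels
    hu = idx[:, :-1]
    hv = idx[:, 1:]
    hok = (hu >= 0) & (hv >= 0)
    vu = idx[:-1, :]
    vv = idx[1:, :]
    vok = (vu >= 0) & (vv >= 0)
    eu = np.concatenate([hu[hok], vu[vok]])
    ev = np.concatenate([hv[hok], vv[vok]])
    eb = np.ones(eu.size, dtype=np.float64)

    thresh = scale * scale
    # fixed pseudo-random tie-break priorities (splitmix-style hash of the id)
    ids = np.arange(n + 1, dtype=np.uint64)
    z = (ids + np.uint64(0x9E3779B97F4A7C15)) * np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(31)
    prio = (z >> np.uint64(1)).astype(np.int64)
    prio[n] = np.iinfo(np.int64).max  # sentinel "no neighbour"

    ecost = np.empty(eu.size, dtype=np.float64)
    changed = np.ones(n, dtype=np.bool_)
    while eu.size:
        _update_costs(eu, ev, eb, ecost, changed, cnt, s, ss, perim, rmin, rmax, cmin, cmax,
                      w, wshape, wcmp)
        best_cost = np.full(n, np.inf)
        best_nb = np.full(n, n, dtype=np.int64)
        best_border = np.zeros(n, dtype=np.float64)
        _best_pass(eu, ev, eb, ecost, prio, thresh, best_cost, best_nb, best_border)
        used = np.zeros(n, dtype=np.bool_)
        merged = _merge_pass(
            best_nb, best_border, parent, cnt, s, ss, perim, rmin, rmax, cmin, cmax, used
        )
        if merged == 0:
            break
        ru = np.empty(eu.size, dtype=np.int64)
        rv = np.empty(ev.size, dtype=np.int64)
        _find_many(parent, eu, ru)
        _find_many(parent, ev, rv)
        keep = ru != rv
        a = np.minimum(ru[keep], rv[keep])
        b = np.maximum(ru[keep], rv[keep])
        key = a * n + b
        uniq, inv = np.unique(key, return_inverse=True)
        eb = np.bincount(inv, weights=eb[keep])
        new_ecost = np.empty(uniq.size, dtype=np.float64)
        new_ecost[inv] = ecost[keep]  # stale only where an endpoint changed
        ecost = new_ecost
        eu = uniq // n
        ev = uniq % n
        changed = np.zeros(n, dtype=np.bool_)
        changed[used] = True

    roots = np.empty(n, dtype=np.int64)
    _find_many(parent, np.arange(n, dtype=np.int64), roots)
    # roots are minimal pixel ids per region -> ascending order == row-major
    # first appearance; compact to labels 1..K
    _, inv = np.unique(roots, return_inverse=True)
    labels = np.zeros(valid.shape, dtype=np.int32)
    labels[valid] = (inv + 1).astype(np.int32)
    return SegmentMap(labels=labels, transform=scene.transform)


# ---------------------------------------------------------------------------
# per-object features


def _neighbor_borders(labels: np.ndarray) -> dict:
    """Shared border lengths (pixel edges) between adjacent objects."""
    pairs = []
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff]).astype(np.int64)
        hi = np.maximum(a[diff], b[diff]).astype(np.int64)
        pairs.append(np.stack([lo, hi], axis=1))
    if not pairs:
        return {}
    allp = np.concatenate(pairs, axis=0)
    nbrs: dict = {}
    if allp.size == 0:
        return nbrs
    key = allp[:, 0] * (labels.max() + 1) + allp[:, 1]
    uniq, counts = np.unique(key, return_counts=True)
    base = labels.max() + 1
    for k, c in zip(uniq, counts):
        a = int(k // base)
        b = int(k % base)
        nbrs.setdefault(a, {})[b] = int(c)
        nbrs.setdefault(b, {})[a] = int(c)
    return nbrs


def _perimeters(labels: np.ndarray) -> np.ndarray:
    """Exposed pixel-edge count per object (index = label)."""
    k = labels.max()
    per = np.zeros(k + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    for sh in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(padded, sh, axis=(0, 1))
        exposed = (padded > 0) & (padded != shifted)
        per += np.bincount(padded[exposed], minlength=k + 1)
    return per


def roundness_of_mask(mask: np.ndarray) -> float:
    """Deviation from a circle: ``1 - 4*pi*A / P**2``, 0 = perfect circle.

    ``P`` is the Crofton-formula boundary length (4 directions), which for a
    rasterised disc closely approaches the true circumference, so a disc
    scores near 0 and elongated or lobed shapes score higher. Clamped at 0.
    """
    area = float(mask.sum())
    p = float(_crofton_perimeter(mask, directions=4))
    if p <= 0:
        return 0.0
    return max(0.0, 1.0 - 4.0 * math.pi * area / (p * p))


def _masked_stats(labels, k, grid, valid=None):
    """Per-label mean over ``grid`` restricted to ``valid`` pixels."""
    lab = labels.ravel()
    g = grid.ravel().astype(np.float64)
    if valid is not None:
        v = valid.ravel()
        cnts = np.bincount(lab, weights=v.astype(np.float64), minlength=k + 1)
        sums = np.bincount(lab, weights=np.where(v, g, 0.0), minlength=k + 1)
    else:
        cnts = np.bincount(lab, minlength=k + 1).astype(np.float64)
        sums = np.bincount(lab, weights=g, minlength=k + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    return means, cnts


def compute_features(
    seg: SegmentMap,
    scene: SceneRaster,
    heights: HeightGrids,
    gv: IndexGrid,
    npv: IndexGrid,
) -> SegmentMap:
    """Fill the per-object feature table and neighbour borders in place."""
    if heights.chm is None:
        heights = compute_chm(heights)
    labels = seg.labels
    k = int(labels.max())
    lab = labels.ravel()
    px = seg.pixel_size

    area = np.bincount(lab, minlength=k + 1)[1:]
    rows_idx, cols_idx = np.indices(labels.shape)

    cols = {}
    for name, grid in (
        ("blue", scene.blue),
        ("green", scene.green),
        ("rededge", scene.rededge),
        ("chm", heights.chm),
    ):
        g = grid.ravel().astype(np.float64)
        sums = np.bincount(lab, weights=g, minlength=k + 1)[1:]
        ssq = np.bincount(lab, weights=g * g, minlength=k + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums / area
            var = np.maximum(ssq / area - mean**2, 0.0)
        cols[f"mean_{name}"] = mean
        cols[f"sd_{name}"] = np.sqrt(var)
    cols["max_chm"] = ndimage.maximum(heights.chm, labels=labels, index=np.arange(1, k + 1))

    mean_gv, _ = _masked_stats(labels, k, gv.values, gv.valid)
    mean_npv, _ = _masked_stats(labels, k, npv.values, npv.valid)
    cols["mean_gv"] = mean_gv[1:]
    cols["mean_npv"] = mean_npv[1:]

    cols["perimeter_px"] = _perimeters(labels)[1:]
    cr, _ = _masked_stats(labels, k, rows_idx)
    cc, _ = _masked_stats(labels, k, cols_idx)
    cols["centroid_row"] = cr[1:]
    cols["centroid_col"] = cc[1:]

    slices = ndimage.find_objects(labels)
    rnd = np.zeros(k)
    bbox = np.zeros((k, 4), dtype=np.int64)
    for i, sl in enumerate(slices):
        if sl is None:
            continue
        mask = labels[sl] == (i + 1)
        rnd[i] = roundness_of_mask(mask)
        bbox[i] = (sl[0].start, sl[0].stop - 1, sl[1].start, sl[1].stop - 1)
    cols["roundness"] = rnd
    cols["rmin"], cols["rmax"], cols["cmin"], cols["cmax"] = bbox.T

    table = pd.DataFrame(cols, index=pd.RangeIndex(1, k + 1, name="label"))
    table.insert(0, "area_px", area)
    table.insert(1, "area_m2", area * px * px)
    table["tag"] = ""
    table = table[table["area_px"] > 0]  # labels may be sparse after relabelling

    seg.table = table
    seg.neighbors = _neighbor_borders(labels)
    seg.grids = {"scene": scene, "heights": heights, "gv": gv, "npv": npv}
    return seg


def _recompute_object(seg: SegmentMap, label: int) -> None:
    """Refresh one table row from the label grid and stashed grids."""
    scene = seg.grids["scene"]
    heights = seg.grids["heights"]
    gv = seg.grids["gv"]
    npv = seg.grids["npv"]
    mask = seg.labels == label
    n = int(mask.sum())
    if n == 0:
        raise KeyError(f"unknown label {label}")
    px = seg.pixel_size
    row = seg.table.loc[label]
    upd = {"area_px": n, "area_m2": n * px * px}
    for name, grid in (
        ("blue", scene.blue),
        ("green", scene.green),
        ("rededge", scene.rededge),
        ("chm", heights.chm),
    ):
        v = grid[mask].astype(np.float64)
        upd[f"mean_{name}"] = v.mean()
        upd[f"sd_{name}"] = v.std()
    upd["max_chm"] = float(heights.chm[mask].max())
    for name, ig in (("mean_gv", gv), ("mean_npv", npv)):
        ok = ig.valid[mask]
        upd[name] = float(ig.values[mask][ok].mean()) if ok.any() else np.nan
    rr, cc = np.nonzero(mask)
    upd["centroid_row"] = rr.mean()
    upd["centroid_col"] = cc.mean()
    upd["rmin"], upd["rmax"] = int(rr.min()), int(rr.max())
    upd["cmin"], upd["cmax"] = int(cc.min()), int(cc.max())
    sub = mask[upd["rmin"]: upd["rmax"] + 1, upd["cmin"]: upd["cmax"] + 1]
    upd["roundness"] = roundness_of_mask(sub)
    padded = np.pad(mask, 1)
    per = 0
    for sh in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        per += int((padded & ~np.roll(padded, sh, axis=(0, 1))).sum())
    upd["perimeter_px"] = per
    for key, v in upd.items():
        seg.table.at[label, key] = v
    _ = row  # silence linters


def merge_objects(seg: SegmentMap, label_a: int, label_b: int) -> SegmentMap:
    """Merge two adjacent objects; the smaller numeric label survives.

    Features of the merged object are recomputed and the neighbour table is
    updated. Raises on unknown or non-adjacent labels.
    """
    if seg.table is None or seg.neighbors is None:
        raise ValueError("compute_features must run before merge_objects")
    for lab in (label_a, label_b):
        if lab not in seg.table.index:
            raise KeyError(f"unknown label {lab}")
    if label_b not in seg.neighbors.get(label_a, {}):
        raise ValueError(f"objects {label_a} and {label_b} are not adjacent")
    keep, drop = sorted((int(label_a), int(label_b)))
    seg.labels[seg.labels == drop] = keep
    seg.table = seg.table.drop(index=drop)
    _recompute_object(seg, keep)

    nbrs = seg.neighbors
    merged_nbrs = {}
    for other, ln in nbrs.pop(keep, {}).items():
        if other != drop:
            merged_nbrs[other] = merged_nbrs.get(other, 0) + ln
    for other, ln in nbrs.pop(drop, {}).items():
        if other != keep:
            merged_nbrs[other] = merged_nbrs.get(other, 0) + ln
    nbrs[keep] = merged_nbrs
    for other in list(nbrs):
        if other == keep:
            continue
        d = nbrs[other]
        if drop in d:
            d[keep] = d.get(keep, 0) + d.pop(drop)
    return seg
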