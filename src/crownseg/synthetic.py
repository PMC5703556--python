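"""Labelled synthetic dry-forest scenes for desk-scale validation.

The generator emulates the structural and spectral signatures the rule set
assumes, over a bright bare-soil background:

* **alive Algarrobo** — star-shaped green crowns (k-lobed, k in 5..8) with a
  moderate red-edge response, placed free-standing;
* **Sapote** — compact elliptical evergreen crowns with a strong red-edge
  response;
* **dead Algarrobo** — large leafless star crowns whose blue-vs-green response
  (NPV) rises toward the crown centre (denser standing wood), tall in the CHM;
  optionally grouped into a tangent cluster;
* **Overo** — low (< 0.4 m) lobed shrub patches strung along sinuous runnel
  curves.

Heights are cosine domes peaking at the crown centre so every green tree has
a unique CHM maximum and every dead crown a unique NPV maximum, which makes
local-extrema seeding well-posed. Bands are rendered on an 8-bit-like digital
number scale (consumer camera); the indices downstream are scale-free ratios.
All randomness flows from one seeded generator, so scenes are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GroundTruthTree, HeightGrids, SceneRaster, Transform

__all__ = ["ClassProfile", "SceneSpec", "GroundTruth", "generate_scene", "truth_plot_counts"]


@dataclass(frozen=True)
class ClassProfile:
    """Mean band response (digital numbers) of one cover class."""

    blue: float
    green: float
    rededge: float
    blue_center_boost: float = 0.0  # added to blue at the crown centre, tapering to 0 at the edge

    def gv(self) -> float:
        return (self.rededge - self.green) / (self.rededge + self.green)

    def npv(self, at_center: bool = False) -> float:
        b = self.blue + (self.blue_center_boost if at_center else 0.0)
        return (b - self.green) / (b + self.green)

    def npv_mean(self) -> float:
        # cone-tapered boost contributes ~1/3 of its centre value to the mean
        b = self.blue + self.blue_center_boost / 3.0
        return (b - self.green) / (b + self.green)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; defaults are the study conditions."""

    extent_m: tuple[float, float] = (95.0, 95.0)
    pixel_size_m: float = 0.083
    rng_seed: int = 0

    n_sapote: int = 17
    n_algarrobo_alive: int = 17
    n_algarrobo_dead: int = 6
    n_overo: int = 6
    dead_cluster_size: int = 3  # of the dead trees, this many form one tangent cluster

    # crown radius ranges (m)
    sapote_radius_m: tuple[float, float] = (1.6, 2.4)
    alive_radius_m: tuple[float, float] = (2.6, 3.6)
    dead_radius_m: tuple[float, float] = (6.8, 7.4)
    overo_radius_m: tuple[float, float] = (1.0, 1.8)  # per lobe; patches are 4-6 lobes

    # height ranges (m)
    sapote_height_m: tuple[float, float] = (3.0, 6.0)
    alive_height_m: tuple[float, float] = (4.0, 9.0)
    dead_height_m: tuple[float, float] = (2.5, 7.0)
    overo_height_m: tuple[float, float] = (0.15, 0.32)

    profiles: dict = field(
        default_factory=lambda: {
            "background": ClassProfile(118.0, 120.0, 122.0),
            "sapote": ClassProfile(60.0, 80.0, 100.8),
            "algarrobo_alive": ClassProfile(70.0, 90.0, 100.5),
            "algarrobo_dead": ClassProfile(112.0, 99.0, 100.0, blue_center_boost=15.0),
            "overo": ClassProfile(112.0, 99.0, 99.5),
        }
    )

    noise_sd: float = 1.5           # additive Gaussian, per band (DN)
    height_noise_sd: float = 0.02   # DSM noise (m)
    sparse_canopy_dropout: float = 0.0  # fraction of dead-crown DSM pixels zeroed (photogrammetric failure)

    min_gap_m: float = 1.0          # bare-soil gap between free-standing crowns
    border_margin_m: float = 4.0    # clearance beyond the crown radius at the scene edge
    plot_margin_m: float = 4.0      # keep crown centres clear of plot boundaries
    max_attempts: int = 4000

    # rule thresholds the profiles must respect, in expectation
    gdvi_threshold: float = 0.03
    sapote_gdvi_min: float = 0.08
    npv_threshold: float = 0.053
    chm_bush_max_m: float = 0.4

    def __post_init__(self) -> None:
        self.validate()

    def to_yaml(self, path) -> None:
        """Serialise to the same flat key:value format the rule config uses."""
        import yaml
        from dataclasses import asdict
        from pathlib import Path

        d = asdict(self)
        d["profiles"] = {k: asdict(v) for k, v in self.profiles.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        import yaml
        from pathlib import Path

        d = yaml.safe_load(Path(path).read_text())
        if "profiles" in d:
            d["profiles"] = {k: ClassProfile(**v) for k, v in d["profiles"].items()}
        for key, v in list(d.items()):
            if isinstance(v, list):
                d[key] = tuple(v)
        return cls(**d)

    def validate(self) -> None:
        if self.pixel_size_m <= 0 or min(self.extent_m) <= 0:
            raise ValueError("extent and pixel size must be positive")
        p = self.profiles
        if not p["sapote"].gv() > self.sapote_gdvi_min:
            raise ValueError("sapote profile must have GV above the sapote threshold")
        if not self.gdvi_threshold < p["algarrobo_alive"].gv() < self.sapote_gdvi_min:
            raise ValueError("alive-Algarrobo GV must sit between the two green thresholds")
        for name in ("algarrobo_dead", "overo"):
            if not p[name].npv_mean() > self.npv_threshold:
                raise ValueError(f"{name} profile must have mean NPV above the NPV threshold")
        bg = p["background"]
        if bg.gv() > self.gdvi_threshold or bg.npv() > self.npv_threshold:
            raise ValueError("background must fall below both vegetation thresholds")
        if not self.dead_height_m[0] > self.chm_bush_max_m > self.overo_height_m[1]:
            raise ValueError("dead trees must exceed, and Overo stay under, the bush height limit")
        if self.dead_cluster_size > self.n_algarrobo_dead:
            raise ValueError("dead_cluster_size exceeds the dead-tree count")
        if self.dead_cluster_size == 1:
            raise ValueError("a cluster needs at least 2 trees (or 0 to disable)")


@dataclass
class GroundTruth:
    """Reference data rendered with the scene: trees, masks and plots."""

    trees: list  # of GroundTruthTree
    mask: np.ndarray  # int32 label grid, tree id per pixel, 0 = none
    plots: pd.DataFrame  # plot_id, x0, y0, x1, y1 (map coords, half-open)
    transform: Transform

    def mask_of(self, tree_id: int) -> np.ndarray:
        return self.mask == tree_id


# ---------------------------------------------------------------------------
# geometry helpers


def _star_dnorm(rr, cc, r0, c0, radius_px, k, phase, a=0.3):
    dy = rr - r0
    dx = cc - c0
    d = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    redge = radius_px * (1.0 - a + a * np.cos(k * (theta - phase)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.where(redge > 0, d / redge, np.inf)
    return dn


def _ellipse_dnorm(rr, cc, r0, c0, a_px, b_px, angle):
    dy = rr - r0
    dx = cc - c0
    xr = dx * math.cos(angle) + dy * math.sin(angle)
    yr = -dx * math.sin(angle) + dy * math.cos(angle)
    return np.sqrt((xr / a_px) ** 2 + (yr / b_px) ** 2)


class _PlacementError(RuntimeError):
    pass


def _sample_position(rng, lo_r, hi_r, lo_c, hi_c, placed, radius, min_gap, forbidden_lines, plot_margin, attempts):
    """Rejection-sample a centre keeping clear of placed crowns and plot lines."""
    for _ in range(attempts):
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        # crown centres keep plot_margin clear of the plot boundary lines
        if any(abs(c - fl) < plot_margin for fl in forbidden_lines[0]):
            continue
        if any(abs(r - fl) < plot_margin for fl in forbidden_lines[1]):
            continue
        ok = True
        for (pr, pc, prad) in placed:
            if (r - pr) ** 2 + (c - pc) ** 2 < (radius + prad + min_gap) ** 2:
                ok = False
                break
        if ok:
            return r, c
    raise _PlacementError(
        "could not place all requested crowns; enlarge the extent or reduce counts"
    )


# ---------------------------------------------------------------------------


def generate_scene(spec: SceneSpec) -> tuple[SceneRaster, HeightGrids, GroundTruth]:
    """Render a labelled scene. Deterministic given ``spec.rng_seed``.

    Crown placement is rejection-sampled; if one arrangement jams, the whole
    layout is retried with a seed-derived substream (still deterministic).
    """
    spec.validate()
    last: _PlacementError | None = None
    for restart in range(8):
        rng = np.random.default_rng([int(spec.rng_seed), restart])
        try:
            return _generate_once(spec, rng)
        except _PlacementError as exc:
            last = exc
    raise last


def _generate_once(spec, rng):
    px = spec.pixel_size_m
    width_m, height_m = spec.extent_m
    W = int(round(width_m / px))
    H = int(round(height_m / px))
    tf = Transform(origin_x=0.0, origin_y=height_m, pixel_size=px)

    # gently sloping bare-earth surface with a low-frequency undulation
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    dem = (
        50.0
        + 0.008 * cols * px
        + 0.004 * rows * px
        + 0.15 * np.sin(2 * np.pi * cols * px / 60.0) * np.cos(2 * np.pi * rows * px / 75.0)
    )

    bg = spec.profiles["background"]
    blue = np.full((H, W), bg.blue)
    green = np.full((H, W), bg.green)
    rededge = np.full((H, W), bg.rededge)
    canopy = np.zeros((H, W))  # height above ground
    truth_mask = np.zeros((H, W), dtype=np.int32)
    dnorm_best = np.full((H, W), np.inf)

    margin_px = spec.border_margin_m / px
    lo = margin_px
    hi_r = H - margin_px
    hi_c = W - margin_px
    # 2x2 quadrant plots; crown centres stay clear of the boundary lines
    plot_lines_c = [W / 2.0]
    plot_lines_r = [H / 2.0]
    plot_margin_px = spec.plot_margin_m / px
    gap_px = spec.min_gap_m / px

    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    trees: list[dict] = []

    def paint(tree_id, dnorm, sl, profile, h_max):
        inside = dnorm <= 1.0
        claim = inside & (dnorm < dnorm_best[sl])
        dnorm_best[sl][claim] = dnorm[claim]
        truth_mask[sl][claim] = tree_id
        blue[sl][claim] = profile.blue + profile.blue_center_boost * (1.0 - dnorm[claim])
        green[sl][claim] = profile.green
        rededge[sl][claim] = profile.rededge
        canopy[sl][claim] = h_max * np.cos(0.5 * np.pi * np.minimum(dnorm[claim], 1.0))

    def bbox_slices(r0, c0, rad_px):
        pad = int(math.ceil(rad_px * 1.35)) + 2
        r_lo = max(0, int(r0) - pad)
        r_hi = min(H, int(r0) + pad)
        c_lo = max(0, int(c0) - pad)
        c_hi = min(W, int(c0) + pad)
        sl = (slice(r_lo, r_hi), slice(c_lo, c_hi))
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        return sl, rr, cc

    next_id = 1

    def add_star_tree(species, r0, c0, rad_px, h_max, health=None, min_area_px=0, phase=None, k=None):
        nonlocal next_id
        if k is None:
            k = int(rng.integers(5, 9))
        if phase is None:
            phase = rng.uniform(0, 2 * np.pi)
        for _ in range(20):
            sl, rr, cc = bbox_slices(r0, c0, rad_px)
            dn = _star_dnorm(rr, cc, r0, c0, rad_px, k, phase)
            area = int((dn <= 1.0).sum())
            if area >= min_area_px:
                break
            rad_px *= 1.03
        prof = spec.profiles[
            "algarrobo_dead" if health == 3 else ("algarrobo_alive" if species == "algarrobo" else species)
        ]
        paint(next_id, dn, sl, prof, h_max)
        trees.append(
            {"id": next_id, "species": species, "health": health, "row": r0, "col": c0}
        )
        placed.append((r0, c0, rad_px))
        next_id += 1

    # --- Overo patches along sinuous runnels ----------------------------------
    runnels = []
    for i in range(2):
        y0 = (rng.uniform(0.18, 0.34) if i == 0 else rng.uniform(0.66, 0.82)) * H
        amp = rng.uniform(0.04, 0.10) * H
        lam = rng.uniform(0.5, 1.0) * W
        ph = rng.uniform(0, 2 * np.pi)
        runnels.append((y0, amp, lam, ph))
    for i in range(spec.n_overo):
        y0, amp, lam, ph = runnels[i % len(runnels)]
        patch_rad = 3.2 / px
        for attempt in range(spec.max_attempts):
            x = rng.uniform(lo + patch_rad, hi_c - patch_rad)
            y = y0 + amp * math.sin(2 * np.pi * x / lam + ph)
            if not (lo + patch_rad < y < hi_r - patch_rad):
                continue
            if any(abs(x - fl) < plot_margin_px for fl in plot_lines_c):
                continue
            if any(abs(y - fl) < plot_margin_px for fl in plot_lines_r):
                continue
            if all(
                (y - pr) ** 2 + (x - pc) ** 2 >= (patch_rad + prad + gap_px) ** 2
                for pr, pc, prad in placed
            ):
                break
        else:
            raise _PlacementError("could not place all Overo patches")
        n_lobes = int(rng.integers(4, 7))
        h = rng.uniform(*spec.overo_height_m)
        sl, rr, cc = bbox_slices(y, x, patch_rad)
        dn = np.full(rr.shape, np.inf)
        step = rng.uniform(0.8, 1.3) / px
        direction = rng.uniform(0, 2 * np.pi)
        cy, cx = y, x
        for j in range(n_lobes):
            lr = rng.uniform(*spec.overo_radius_m) / px
            dn = np.minimum(dn, np.hypot(rr - cy, cc - cx) / lr)
            direction += rng.uniform(-0.7, 0.7)
            cy += step * math.sin(direction)
            cx += step * math.cos(direction)
        paint(next_id, dn, sl, spec.profiles["overo"], h)
        trees.append({"id": next_id, "species": "overo", "health": None, "row": y, "col": x})
        placed.append((y, x, patch_rad))
        next_id += 1


    # --- dead Algarrobo: one tangent cluster first, then singles -------------
    n_dead = spec.n_algarrobo_dead
    n_cluster = spec.dead_cluster_size if n_dead >= spec.dead_cluster_size >= 2 else 0
    if n_cluster:
        from scipy import ndimage as _ndi

        radii = rng.uniform(*spec.dead_radius_m, size=n_cluster) / px
        cluster_rad = 2.05 * float(np.max(radii))
        r0, c0 = _sample_position(
            rng, lo + cluster_rad, hi_r - cluster_rad, lo + cluster_rad, hi_c - cluster_rad,
            placed, cluster_rad, gap_px, (plot_lines_c, plot_lines_r),
            plot_margin_px + 1.05 * float(np.max(radii)), spec.max_attempts,
        )
        base = rng.uniform(0, 2 * np.pi)
        ks = [int(rng.integers(5, 9)) for _ in range(n_cluster)]
        # every member points one star lobe at the cluster centre, so the
        # union is 4-connected; grow radii until the union safely exceeds the
        # isolated-vs-cluster area threshold
        min_union_px = int(31500 * (0.083 / px) ** 2)
        for _ in range(25):
            members = []
            for i in range(n_cluster):
                ang = base + 2 * np.pi * i / n_cluster
                d = 0.9 * radii[i]
                rr0 = r0 + d * math.sin(ang)
                cc0 = c0 + d * math.cos(ang)
                members.append((rr0, cc0, radii[i], ang + np.pi, ks[i]))
            pad = int(2.4 * max(radii)) + 2
            rr, cc = np.mgrid[int(r0) - pad: int(r0) + pad, int(c0) - pad: int(c0) + pad]
            union = np.zeros(rr.shape, dtype=bool)
            for rr0, cc0, rad, phase, k in members:
                union |= _star_dnorm(rr, cc, rr0, cc0, rad, k, phase) <= 1.0
            _, ncomp = _ndi.label(union)
            if union.sum() >= min_union_px and ncomp == 1:
                break
            radii = radii * 1.04
        for rr0, cc0, rad, phase, k in members:
            h = rng.uniform(*spec.dead_height_m)
            add_star_tree("algarrobo", rr0, cc0, rad, h, health=3, phase=phase, k=k)
        placed.append((r0, c0, cluster_rad))
    for _ in range(n_dead - n_cluster):
        rad = rng.uniform(*spec.dead_radius_m) / px
        r0, c0 = _sample_position(
            rng, lo + rad, hi_r - rad, lo + rad, hi_c - rad, placed, rad, gap_px,
            (plot_lines_c, plot_lines_r), plot_margin_px, spec.max_attempts,
        )
        h = rng.uniform(*spec.dead_height_m)
        add_star_tree("algarrobo", r0, c0, rad, h, health=3,
                      min_area_px=int(10500 * (0.083 / px) ** 2))

    # --- alive Algarrobo ------------------------------------------------------
    for _ in range(spec.n_algarrobo_alive):
        rad = rng.uniform(*spec.alive_radius_m) / px
        r0, c0 = _sample_position(
            rng, lo + rad, hi_r - rad, lo + rad, hi_c - rad, placed, rad, gap_px,
            (plot_lines_c, plot_lines_r), plot_margin_px, spec.max_attempts,
        )
        h = rng.uniform(*spec.alive_height_m)
        health = int(rng.integers(1, 3))  # 1 healthy or 2 infected, both alive
        add_star_tree("algarrobo", r0, c0, rad, h, health=health)

    # --- Sapote ---------------------------------------------------------------
    for _ in range(spec.n_sapote):
        rad = rng.uniform(*spec.sapote_radius_m) / px
        r0, c0 = _sample_position(
            rng, lo + rad, hi_r - rad, lo + rad, hi_c - rad, placed, rad, gap_px,
            (plot_lines_c, plot_lines_r), plot_margin_px, spec.max_attempts,
        )
        squash = rng.uniform(0.8, 1.0)
        angle = rng.uniform(0, np.pi)
        h = rng.uniform(*spec.sapote_height_m)
        sl, rr, cc = bbox_slices(r0, c0, rad)
        dn = _ellipse_dnorm(rr, cc, r0, c0, rad, rad * squash, angle)
        paint(next_id, dn, sl, spec.profiles["sapote"], h)
        trees.append({"id": next_id, "species": "sapote", "health": None, "row": r0, "col": c0})
        placed.append((r0, c0, rad))
        next_id += 1

    # --- surfaces and noise ----------------------------------------------------
    dsm = dem + canopy
    if spec.sparse_canopy_dropout > 0:
        dead_ids = [t["id"] for t in trees if t["health"] == 3]
        if dead_ids:
            dead_px = np.isin(truth_mask, dead_ids)
            drop = dead_px & (rng.random((H, W)) < spec.sparse_canopy_dropout)
            dsm[drop] = dem[drop]
    if spec.noise_sd > 0:
        blue = blue + rng.normal(0.0, spec.noise_sd, (H, W))
        green = green + rng.normal(0.0, spec.noise_sd, (H, W))
        rededge = rededge + rng.normal(0.0, spec.noise_sd, (H, W))
    if spec.height_noise_sd > 0:
        dsm = dsm + rng.normal(0.0, spec.height_noise_sd, (H, W))
    blue = np.clip(blue, 0.0, None)
    green = np.clip(green, 0.0, None)
    rededge = np.clip(rededge, 0.0, None)

    scene = SceneRaster(blue=blue, green=green, rededge=rededge, transform=tf, crs_tag="local")
    heights = HeightGrids(dem=dem, dsm=dsm, transform=tf)

    # --- ground truth ----------------------------------------------------------
    plots = pd.DataFrame(
        [
            {"plot_id": 1, "x0": 0.0, "y0": height_m / 2, "x1": width_m / 2, "y1": height_m},
            {"plot_id": 2, "x0": width_m / 2, "y0": height_m / 2, "x1": width_m, "y1": height_m},
            {"plot_id": 3, "x0": 0.0, "y0": 0.0, "x1": width_m / 2, "y1": height_m / 2},
            {"plot_id": 4, "x0": width_m / 2, "y0": 0.0, "x1": width_m, "y1": height_m / 2},
        ]
    )
    gt_trees = []
    for t in trees:
        m = truth_mask == t["id"]
        area_m2 = float(m.sum()) * px * px
        if area_m2 <= 0:
            continue
        x, y = tf.pixel_center(t["row"], t["col"])
        plot_id = None
        for p in plots.itertuples():
            if p.x0 <= x < p.x1 and p.y0 <= y < p.y1:
                plot_id = int(p.plot_id)
                break
        gt_trees.append(
            GroundTruthTree(
                id=t["id"],
                species=t["species"],
                crown_spread_m2=area_m2,
                centroid=(float(x), float(y)),
                plot_id=plot_id,
                health_grade=t["health"],
            )
        )
    truth = GroundTruth(trees=gt_trees, mask=truth_mask, plots=plots, transform=tf)
    return scene, heights, truth


TREE_CLASSES = ("sapote", "algarrobo_alive", "algarrobo_dead")


def truth_species_class(tree: GroundTruthTree) -> str:
    """Map a surveyed tree to its reference map class (health 1-2 alive, 3 dead)."""
    if tree.species == "algarrobo":
        return "algarrobo_dead" if tree.health_grade == 3 else "algarrobo_alive"
    return tree.species


def truth_plot_counts(
    truth: GroundTruth, plots: pd.DataFrame | None = None, min_crown_m2: float = 4.0
) -> pd.DataFrame:
    """Per-plot reference counts with the survey filters applied.

    Crowns of at most ``min_crown_m2`` are excluded; Algarrobo health grades
    1-2 count as alive and 3 as dead; Overo is tallied as present patches,
    not as trees.
    """
    plots = truth.plots if plots is None else plots
    counts = pd.DataFrame(
        0,
        index=pd.Index(plots["plot_id"].astype(int), name="plot_id"),
        columns=list(TREE_CLASSES) + ["overo_patches"],
    )
    for t in truth.trees:
        if not t.crown_spread_m2 > min_crown_m2:
            continue
        plot_id = None
        for p in plots.itertuples():
            if p.x0 <= t.centroid[0] < p.x1 and p.y0 <= t.centroid[1] < p.y1:
                plot_id = int(p.plot_id)
                break
        if plot_id is None:
            continue
        cls = truth_species_class(t)
        if cls == "overo":
            counts.at[plot_id, "overo_patches"] += 1
        elif cls in TREE_CLASSES:
            counts.at[plot_id, cls] += 1
    return counts
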