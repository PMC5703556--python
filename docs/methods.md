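# Methods

This note documents the models, parameters and numerical choices behind
`crownseg`, and what the synthetic validation does and does not demonstrate.

## The mapping problem

The target landscape is an open, disturbed dry-forest bajada in Northern
Peru: free-standing mature crowns and occasional interconnected tree
clusters of four dominant cover types — Sapote (compact, round/sub-oval
evergreen crowns), alive Algarrobo (star-shaped crowns, partially defoliated
when infested), dead Algarrobo (large leafless star crowns) and the low
Overo shrub (< 2 m, reticulated patches along ephemeral runnels). Inputs are
a 3-band orthomosaic (blue, green, red-edge; ~8.3 cm pixels from a
filter-modified consumer camera) and photogrammetric DSM/DEM grids on the
same grid. The deliverables are one polygon per tree crown, a 4-class label
per crown, accuracy statistics and fishnet landscape metrics.

## Indices and CHM

`GV = (RE − G)/(RE + G)` (called GDVI in the rule set) rises with
photosynthetic canopy because reflectance climbs steeply across the red
edge; `NPV = (B − G)/(B + G)` rises for grey, leafless canopies. Both are
ratios, so the pipeline is agnostic to whether bands are digital numbers or
reflectances; the thresholds (0.053, 0.03, 0.08) assume the DN scale of the
original survey and are configurable. `CHM = max(DSM − DEM, 0)`; negative
photogrammetric differences are clamped, divisions happen in float
regardless of input integer types, and any nodata input propagates.

## Multiresolution segmentation

Bottom-up pairwise region merging in the Baatz–Schäpe tradition over four
layers (B, G, RE, CHM; weights 1/1/1/1 by default). The merge cost is

```
f = (1 − w_shape) · Σ_b w_b (n_m σ_m,b − n_1 σ_1,b − n_2 σ_2,b)
  +      w_shape  · [ w_cmpct h_cmpct + (1 − w_cmpct) h_smooth ]
```

with `h_cmpct` and `h_smooth` the same extensive differences of `P/√n`
(perimeter over root area) and `P/P_bbox`. A merge is admissible while
`f < scale²`. Merging proceeds by local mutual best fit in synchronous
rounds: each region nominates its cheapest admissible neighbour and mutually
nominating pairs merge; rounds repeat to a fixed point, making the result
deterministic and traversal-order independent.

Numerical choices:

* **Tie-breaking.** On homogeneous areas many candidate merges cost exactly
  the same. Breaking ties toward the smallest region id creates long
  one-directional nomination chains (each region points left/up), with a
  single mutual pair per chain — convergence then needs O(n) rounds. Ties
  are instead broken on a fixed pseudo-random priority (a splitmix-style
  hash of the region id, id as the final tie-break), which turns tie
  plateaus into near-random matchings and converges in a few dozen rounds.
  Fully deterministic.
* **Scale/shape/compactness** are not published; defaults are
  eCognition-style starting values (20 / 0.1 / 0.5), exposed in the config.
  The scale parameter is unit-dependent; with 8-bit-like band values the
  default behaves as in common OBIA practice.
* Objects are 4-connected; borders are counted in shared pixel edges; the
  per-edge cost cache is refreshed only for regions whose statistics
  changed; kernels are numba-compiled.
* **Roundness** (used by the isolated-vs-cluster split) is not defined in
  the source rule set. It is implemented as deviation from a circle,
  `1 − 4πA/P²` with `P` the Crofton-formula (4-direction) boundary length,
  clamped at 0: a rasterised disc scores ≈ 0.02, a 6-lobed star ≈ 0.7, so
  the threshold 0.9 (smaller = rounder) admits single crowns of both shapes
  and rejects only very elongated or ramified objects.

## Level 1 — vegetation objects and the isolated/cluster split

Object tagging: mean NPV > 0.053 → non-photosynthetic vegetation (tested
first, since dead canopies can also show weak GV); else mean GV > 0.03 →
green vegetation; else background. Adjacent same-tag vegetation objects are
merged (the merged means are weighted means of the parts, so tags are
stable); background objects whose entire neighbourhood is one vegetation
object and which do not touch the raster border are absorbed as crown
interior; vegetation under the 4 m² minimum mapping unit is dropped.
Vegetation objects with roundness < 0.9 **and** area < 30,000 px are
isolated crowns; anything larger or less compact is a tree cluster.

## Level 2 — de-clustering

Seeds are strict local maxima of a guiding surface inside the cluster,
searched in a square window (half-width 50 px for green vegetation on the
CHM; 20 px for non-photosynthetic vegetation on NPV — photogrammetric point
clouds are too sparse over leafless branches for CHM maxima, which is also
why NPV-mode seeds may sit on CHM-nodata pixels). Plateau ties go to the
lexicographically first pixel.

The guiding surface is pre-smoothed by a Gaussian (σ = 2 px by default,
normalised convolution restricted to the cluster, configurable, 0 disables).
Without it, per-pixel sensor noise both litters the window search with
spurious maxima and destabilises growth: the growth priority
`|value − seed value|` becomes a global race in which the region whose seed
value sits closest to the bulk of the noisy values annexes the entire
cluster. Smoothing restores the noise-free behaviour; it is the same
standard step taken before local-maxima treetop detection on CHMs.

Growing is best-first: repeatedly assign the unassigned cluster pixel
4-adjacent to a region whose guiding value differs least from that region's
seed value; ties break on (row, col, region index), so growth is
deterministic. The result partitions the cluster; sub-MMU fragments merge
into the neighbour with the longest shared border; a seedless cluster is
returned as a single crown with a logged warning.

Contextual refinement: a crown whose relative border (shared border over its
total border) to a single neighbouring crown of the *other* vegetation kind
exceeds 0.5 is absorbed into that neighbour — the signature of an infested
Algarrobo delineated as separate dead and leafy parts. Applied once, largest
relative border first. The 0.5 threshold is not published and is exposed in
the config.

## Species rules

Green crowns: GV ≥ 0.08 → Sapote, else alive Algarrobo (boundary to Sapote,
matching the paired "< 0.08" alive rule). NPV crowns: area ≥ 10,000 px and
CHM > 0.4 m → dead Algarrobo; area < 10,000 px and CHM < 0.4 m → Overo. The
two unruled quadrants (small-and-tall, large-and-short) are resolved by the
height test alone — tree versus bush is the biologically decisive
distinction — with a logged warning; this matters in practice because
region-grown members of a dead cluster can individually fall under the area
threshold. The CHM statistic for the 0.4 m rule is the object maximum (tree
top) by default, configurable to the mean. Overo is mapped but excluded
from all tree counts.

## Accuracy machinery

Detection is assessed non-site-specifically: classified and reference counts
are compared per plot and summed — no tree-to-tree matching — and the rate
is `100 · classified/reference` per class and overall. Reference counts
apply the survey filters: crowns above 4 m² only; Algarrobo health grades
1–2 count as alive, 3 as dead; Overo is tallied as present patches.
Abundances are adjusted as `round_half_up(raw/(rate/100))`; adjusting a
class's classified count by its own rate recovers the reference count
exactly up to rounding (tested as a property). The error matrix (rows =
classified, columns = reference) yields producer's accuracy
(diagonal/column total), user's accuracy (diagonal/row total) and overall
accuracy (trace/grand total); undefined ratios are reported as NaN, never 0.
Overall accuracy equals the classified-count-weighted mean of user's
accuracies — asserted on random matrices.

For synthetic evaluation the error matrix needs labels in correspondence:
each predicted crown is matched to the truth tree with the largest footprint
overlap, ties to the nearest centroid; this matching rule is this package's
own (detection rates never use it).

One published cell is not reproducible: the surveyed alive-Algarrobo
adjusted count (1122) differs from raw/rate = 1331/(59/51) → 1151. Reports
flag the class as "published rule ambiguous" instead of matching the printed
number. Published density and percentage columns are reproduced exactly from
the published adjusted counts.

## Landscape metrics

Fishnet cells (50 m squares, 2500 m²) are anchored at the extent's
lower-left corner (anchor configurable; the original grid origin is
unstated); partial edge cells are kept and flagged. Counts use
centroid-in-cell with half-open cells (left/bottom inclusive), so every
centroid lands in exactly one cell; crown cover clips crown polygons to the
cells, conserving total crown area; percent dead Algarrobo is
dead/(dead + alive) per cell, undefined (NaN) where a cell has no Algarrobo.
Percentages are reported rounded to integers and densities to 0.1 trees/ha,
with full precision retained alongside.

## Synthetic scenes — what they emulate, and what they do not

The generator renders, over a bright bare-soil background on a gently
sloping DEM: elliptical Sapote crowns (GV ≈ 0.115), star-shaped alive
Algarrobo (5–8 lobes, GV ≈ 0.055), large star-shaped dead Algarrobo whose
blue response rises toward the crown centre (NPV ≈ 0.06 at the edge to
≈ 0.12 at the centre — denser standing wood — giving each dead crown a
unique NPV maximum), and low Overo patches (NPV ≈ 0.06, < 0.4 m) strung
along two sinusoidal runnel curves. Heights are cosine domes, so every
green tree has a unique CHM apex. Bands are on an 8-bit-like DN scale with
additive Gaussian noise (σ = 1.5 DN per band, 2 cm on the DSM by default);
a "sparse point cloud" mode (off by default) zeroes random dead-crown DSM
pixels to emulate photogrammetric failure over leafless canopies.

Default scene: 95 × 95 m at 8.3 cm (≈ 1.3 Mpx), 17 Sapote, 17 alive and 6
dead Algarrobo (three of the dead as one tangent cluster whose star lobes
point at the cluster centre, guaranteeing a 4-connected union above the
30,000 px cluster threshold) and 6 Overo patches — 40 trees, the scale at
which the whole pipeline runs in seconds. Placement is rejection-sampled
with separation constraints (crown centres also keep clear of plot
boundaries so centroid-in-plot counting is unambiguous); a jammed layout is
retried deterministically from a seed-derived substream. All randomness
comes from one seeded generator; scenes are bit-reproducible.

Green tangent *pairs* are deliberately absent from the default scene: two
touching green crowns merge into one compact object of well under 30,000 px,
which the published Level-1 thresholds route to the isolated branch — the
rule set simply cannot split such pairs. Green-cluster de-clustering is
validated separately on constructed clusters forced down the cluster branch.

Passing synthetic tests therefore demonstrates the internal consistency of
the rule set and the correctness of every algorithmic stage under the
signatures the classifier assumes. It does not demonstrate field radiometric
realism: profiles are chosen to satisfy the threshold orderings, not
measured in Peru; crowns are geometric idealisations; mixed
sub-canopy vegetation (the main published confusion source) is not
simulated.

## Problem sizes and tolerances

Survey statistics are exact arithmetic on the printed counts (441 validation
trees, 214 reference trees, 2578 mapped crowns) and reproduce every printed
cell at printed precision except the flagged alive-Algarrobo adjustment.
Synthetic validation runs the full pipeline on the default scene: noise-free
recovery is exact (detection 100%, per-crown classification 100%); under
default noise, aggregate detection and classification over ten seeds stay
within a few percent of 100. The acceptance script uses one noise-free plus
three noisy scenes. Feature means match brute-force accumulation to 1e-12
relative; fishnet clipping conserves area to 1e-6 relative; a rasterised
disc's roundness is within 0.05 of the ideal 0.

## Known limitations

* The segmentation scale parameter of the original survey is unrecoverable;
  nothing here depends on matching proprietary segment geometry.
* Radiometric calibration is out of scope; thresholds assume the original
  DN scale and must be re-tuned for reflectance products.
* The region-growing criterion is a concretisation (the original workflow's
  grow-region internals are unpublished): value-proximity to the seed with
  Gaussian pre-smoothing.
* Only 3-band scenes, square north-up pixels, and a single nodata sentinel
  per raster are supported; no reprojection.
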