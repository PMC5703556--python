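# crownseg

Individual tree-crown delineation and species classification from
very-high-resolution UAV imagery, by object-based image analysis (OBIA).

`crownseg` operationalises a two-level OBIA workflow developed for the
Pacific Equatorial dry forest of Northern Peru, where the keystone tree
*Prosopis pallida* (Algarrobo) is suffering severe die-back. From a 3-band
orthomosaic (blue, green, red-edge — a filter-modified consumer camera at
~8.3 cm ground resolution) plus photogrammetric DSM/DEM grids, it delineates
every tree crown, classifies each into four classes — Sapote
(*Colicodendron scabridum*), alive Algarrobo, dead Algarrobo and the Overo
shrub (*Cordia lutea*) — and produces the accuracy statistics (plot-level
detection rates, error matrix with producer's/user's/overall accuracy,
detection-adjusted abundances) and landscape metrics (50 m fishnet counts,
crown cover, Algarrobo mortality) that make the map usable for conservation
monitoring. A synthetic-scene generator renders labelled scenes with the
same spectral/structural signatures, so the whole pipeline is testable
without UAV flights.

## Method

Two band ratios separate vegetation from the bright bare soil:

```
GV  (GDVI) = (RE − G) / (RE + G)      green vegetation (red-edge rise)
NPV        = (B − G) / (B + G)        non-photosynthetic vegetation
```

and a canopy height model `CHM = max(DSM − DEM, 0)` supplies structure.

**Level 1** — a multiresolution segmentation (Baatz–Schäpe-style bottom-up
region merging over B, G, RE and CHM, weighted 1/1/1/1, stopped when the
cheapest merge cost exceeds `scale²`) yields object candidates. Objects with
mean NPV > 0.053 are tagged non-photosynthetic vegetation, otherwise mean
GV > 0.03 tags green vegetation; adjacent same-tag objects merge, enclosed
background holes are absorbed, and objects under the 4 m² minimum mapping
unit are dropped. Vegetation objects that are compact and modest in extent
(roundness < 0.9, area < 30,000 px) are isolated crowns; the rest are tree
clusters.

**Level 2** — clusters are de-clustered from seed pixels: CHM local maxima
(window half-width 50 px) for green vegetation, NPV local maxima (half-width
20 px) for leafless/dead vegetation, whose sparse branches defeat
photogrammetric height models. Best-first region growing assigns every
cluster pixel to the seed whose guiding value it matches most closely, and a
contextual pass merges mixed-kind crown fragments sharing most of their
border (an infested tree split into dead and leafy parts).

**Classification** — green crowns: GV ≥ 0.08 → Sapote, else alive Algarrobo;
NPV crowns: area ≥ 10,000 px and CHM > 0.4 m → dead Algarrobo, small and low
→ Overo (mapped but not counted as a tree).

## Worked example

Run the full pipeline on a generated scene (all stages also exist as
subcommands: `simulate`, `indices`, `segment`, `delineate`, `classify`,
`assess`, `metrics`):

```
$ crownseg run --synthetic --seed 3 --outdir out/
overall detection rate: 100.00%
overall classification accuracy: 100.00%
crowns: 46; per-class counts: {'sapote': 17, 'overo': 6, 'algarrobo_alive': 17, 'algarrobo_dead': 6}
outputs in out/
```

The scene holds 40 trees (17 Sapote, 17 alive and 6 dead Algarrobo, three of
the dead forming one tangent cluster) plus 6 Overo patches; the pipeline
recovers one crown per tree and labels every crown correctly. `out/`
contains the crowns as GeoJSON with per-crown features, per-class and
fishnet summary tables, and a JSON manifest (inputs, config hash, seed,
stage timings) that makes the run reproducible bit-for-bit.

`crownseg reproduce-tables` recomputes the published survey statistics from
the embedded raw counts of the 80 ha Peruvian survey and prints them beside
the published values:

```
$ crownseg reproduce-tables
Detection rates (classified / reference):
  sapote               94.73684%  published   94.73684%  [match]
  ...
Error-matrix accuracies:
  overall              94.10%  published   94.10%  [match]
  ...
```

Every derived cell matches, except the published adjusted alive-Algarrobo
count, which does not follow the stated adjustment rule and is flagged
`published rule ambiguous` rather than matched.

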