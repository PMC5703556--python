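"""Raster and vector I/O.

Rasters are GeoTIFFs: plain TIFF payloads carrying the standard georeferencing
tags (ModelPixelScale 33550, ModelTiepoint 33922, GeoAsciiParams 34737 and the
GDAL nodata tag 42113), written and read with :mod:`tifffile`. Only square,
north-up pixels are supported — no reprojection engine. Vectors (crowns,
fishnet cells, ground truth) are GeoJSON in map coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping, shape as shapely_shape

from .types import HeightGrids, SceneRaster, Transform, NODATA_DEFAULT

__all__ = [
    "read_raster",
    "write_raster",
    "read_scene",
    "write_scene",
    "write_crowns",
    "read_crowns",
    "write_ground_truth",
    "read_ground_truth",
]

logger = logging.getLogger("crownseg")

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


def write_raster(
    path: str | Path,
    data: np.ndarray,
    transform: Transform,
    crs_tag: str = "local",
    nodata: float = NODATA_DEFAULT,
) -> None:
    """Write a (H, W) or (H, W, bands) grid as a georeferenced TIFF."""
    px = transform.pixel_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)),
        (_TAG_GEO_ASCII, "s", 0, crs_tag + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    kwargs = {}
    if data.ndim == 2:
        kwargs["photometric"] = "minisblack"
    elif data.ndim == 3 and data.shape[2] == 3:
        kwargs["photometric"] = "rgb"
    tifffile.imwrite(str(path), np.ascontiguousarray(data), extratags=extratags, **kwargs)


def read_raster(path: str | Path) -> tuple[np.ndarray, Transform, str, float]:
    """Read a georeferenced TIFF; returns (data, transform, crs_tag, nodata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
        i, j, _k, x, y, _z = (float(v) for v in tie.value[:6])
        origin_x = x - j * sx
        origin_y = y + i * sy
        crs_raw = tags.get(_TAG_GEO_ASCII)
        crs_tag = str(crs_raw.value).rstrip("|") if crs_raw is not None else "local"
        nod_raw = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nod_raw.value) if nod_raw is not None else NODATA_DEFAULT
    return data, Transform(origin_x, origin_y, sx), crs_tag, nodata


def _resample_nearest(
    src: np.ndarray, src_tf: Transform, dst_shape: tuple[int, int], dst_tf: Transform, nodata: float
) -> np.ndarray:
    """Nearest-neighbour resampling of ``src`` onto the destination grid."""
    rows = np.arange(dst_shape[0])
    cols = np.arange(dst_shape[1])
    # map coords of destination pixel centres
    xs = dst_tf.origin_x + (cols + 0.5) * dst_tf.pixel_size
    ys = dst_tf.origin_y - (rows + 0.5) * dst_tf.pixel_size
    sc = np.floor((xs - src_tf.origin_x) / src_tf.pixel_size).astype(np.int64)
    sr = np.floor((src_tf.origin_y - ys) / src_tf.pixel_size).astype(np.int64)
    out = np.full(dst_shape, nodata, dtype=np.float64)
    ok_c = (sc >= 0) & (sc < src.shape[1])
    ok_r = (sr >= 0) & (sr < src.shape[0])
    rr = sr[ok_r][:, None]
    cc = sc[ok_c][None, :]
    out[np.ix_(ok_r, ok_c)] = src[rr, cc]
    return out


def read_scene(
    multiband_path: str | Path, dsm_path: str | Path, dem_path: str | Path
) -> tuple[SceneRaster, HeightGrids]:
    """Load the 3-band mosaic plus DSM/DEM, aligning heights to the mosaic grid.

    Height grids whose transform differs from the mosaic's are resampled to it
    by nearest neighbour with a logged warning; an unreconcilable CRS mismatch
    is an error.
    """
    data, tf, crs, nodata = read_raster(multiband_path)
    if data.ndim == 3 and data.shape[0] in (2, 3, 4, 5) and data.shape[2] not in (2, 3, 4, 5):
        data = np.moveaxis(data, 0, -1)  # accept band-first layouts
    if data.ndim != 3 or data.shape[2] != 3:
        nb = 1 if data.ndim == 2 else data.shape[2]
        raise ValueError(f"expected 3 bands in {multiband_path}, got {nb}")
    blue = data[..., 0].astype(np.float64)
    green = data[..., 1].astype(np.float64)
    rededge = data[..., 2].astype(np.float64)
    scene = SceneRaster(blue, green, rededge, tf, crs_tag=crs, nodata=nodata)

    grids = {}
    for name, path in (("dsm", dsm_path), ("dem", dem_path)):
        g, gtf, gcrs, gnodata = read_raster(path)
        if g.ndim != 2:
            raise ValueError(f"{name} must be single-band, got shape {g.shape}")
        g = g.astype(np.float64)
        if gcrs != crs:
            raise ValueError(f"CRS mismatch: mosaic {crs!r} vs {name} {gcrs!r}")
        if gnodata != nodata:
            g = np.where(g == gnodata, nodata, g)
        if g.shape != scene.shape or not gtf.close_to(tf):
            logger.warning(
                "%s grid not co-registered with mosaic (shape %s vs %s); "
                "resampling by nearest neighbour",
                name, g.shape, scene.shape,
            )
            g = _resample_nearest(g, gtf, scene.shape, tf, nodata)
        grids[name] = g
    heights = HeightGrids(dem=grids["dem"], dsm=grids["dsm"], transform=tf, nodata=nodata)
    return scene, heights


def write_scene(scene: SceneRaster, heights: HeightGrids, outdir: str | Path) -> dict[str, Path]:
    """Write the scene as mosaic.tif / dsm.tif / dem.tif; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "multiband": outdir / "mosaic.tif",
        "dsm": outdir / "dsm.tif",
        "dem": outdir / "dem.tif",
    }
    stack = np.stack([scene.blue, scene.green, scene.rededge], axis=-1)
    write_raster(paths["multiband"], stack, scene.transform, scene.crs_tag, scene.nodata)
    write_raster(paths["dsm"], heights.dsm, scene.transform, scene.crs_tag, heights.nodata)
    write_raster(paths["dem"], heights.dem, scene.transform, scene.crs_tag, heights.nodata)
    return paths


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)

_CROWN_FIELDS = ("id", "class", "area_m2", "mean_gdvi", "mean_npv", "max_chm")


def write_crowns(crowns: Sequence, path: str | Path) -> None:
    """Write delineated crowns as a GeoJSON FeatureCollection.

    Each crown must expose ``id``, ``polygon`` (shapely, map coords), a class
    label and the summary features listed in ``_CROWN_FIELDS``.
    """
    path = Path(path)
    if path.suffix.lower() not in (".geojson", ".json"):
        raise ValueError(f"unsupported vector format {path.suffix!r}; use .geojson")
    features = []
    for c in crowns:
        props = {
            "id": int(c.id),
            "class": c.label,
            "area_m2": float(c.area_m2),
            "mean_gdvi": float(c.features.get("mean_gv", np.nan)),
            "mean_npv": float(c.features.get("mean_npv", np.nan)),
            "max_chm": float(c.features.get("max_chm", np.nan)),
            "vegetation_kind": c.vegetation_kind,
            "provenance": c.provenance,
        }
        features.append(
            {"type": "Feature", "geometry": mapping(c.polygon), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(fc))


def read_crowns(path: str | Path) -> list[dict]:
    """Read crowns back as dicts with shapely ``polygon`` plus attributes."""
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc.get("features", []):
        rec = dict(feat["properties"])
        rec["polygon"] = shapely_shape(feat["geometry"])
        out.append(rec)
    return out


def write_cells(cells, path: str | Path) -> None:
    """Fishnet cells (with any summary columns) as a GeoJSON FeatureCollection."""
    features = []
    for idx, row in cells.iterrows():
        props = {"cell_id": int(idx)}
        for key, v in row.items():
            if key == "geometry":
                continue
            if hasattr(v, "item"):
                v = v.item()
            if isinstance(v, float) and v != v:  # NaN -> null
                v = None
            props[key] = v
        features.append(
            {"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_ground_truth(trees: Iterable, path: str | Path) -> None:
    """Ground-truth trees as GeoJSON points with survey attributes."""
    features = []
    for t in trees:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(t.centroid)},
                "properties": {
                    "id": int(t.id),
                    "species": t.species,
                    "crown_spread_m2": float(t.crown_spread_m2),
                    "health_grade": t.health_grade,
                    "plot_id": t.plot_id,
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_ground_truth(path: str | Path) -> list:
    from .types import GroundTruthTree

    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc.get("features", []):
        p = feat["properties"]
        out.append(
            GroundTruthTree(
                id=p["id"],
                species=p["species"],
                crown_spread_m2=p["crown_spread_m2"],
                centroid=tuple(feat["geometry"]["coordinates"]),
                plot_id=p.get("plot_id"),
                health_grade=p.get("health_grade"),
            )
        )
    return out
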