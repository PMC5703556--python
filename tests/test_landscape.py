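"""Fishnet construction, zonal statistics and area-wide densities."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from crownseg import density_summary, make_fishnet, summarize_cells
from crownseg.classify import ClassifiedMap
from crownseg import reference_survey as rs


class FakeCrown:
    def __init__(self, x, y, label, radius=2.0):
        self.centroid_map = (x, y)
        self.label = label
        self.polygon = Point(x, y).buffer(radius, quad_segs=64)
        self.area_m2 = self.polygon.area


class TestMakeFishnet:
    def test_square_extent(self):
        cells = make_fishnet((0, 0, 100, 100), 50)
        assert len(cells) == 4
        assert not cells["partial"].any()

    def test_partial_edge_cells_flagged(self):
        cells = make_fishnet((0, 0, 120, 100), 50)
        assert len(cells) == 6
        assert cells["partial"].sum() == 2

    def test_cells_tile_extent_without_overlap(self):
        cells = make_fishnet((3, 7, 123, 97), 50)
        total = sum(g.area for g in cells["geometry"])
        assert total == pytest.approx(120 * 90)
        from shapely.ops import unary_union

        assert unary_union(list(cells["geometry"])).area == pytest.approx(120 * 90)


class TestSummarize:
    def test_single_crown_single_cell(self):
        cells = make_fishnet((0, 0, 100, 100), 50)
        cm = ClassifiedMap(crowns=[FakeCrown(25, 75, "sapote")])
        out = summarize_cells(cm, cells)
        assert out["n_sapote"].sum() == 1
        hit = out[out["n_sapote"] == 1].iloc[0]
        assert hit["x0"] == 0 and hit["y0"] == 50

    def test_counts_match_bruteforce_point_in_rectangle(self):
        rng = np.random.default_rng(3)
        cells = make_fishnet((0, 0, 150, 100), 50)
        crowns = [
            FakeCrown(rng.uniform(1, 149), rng.uniform(1, 99), "algarrobo_alive")
            for _ in range(60)
        ]
        out = summarize_cells(ClassifiedMap(crowns=crowns), cells)
        for idx, cell in cells.iterrows():
            n = sum(
                1
                for c in crowns
                if cell.x0 <= c.centroid_map[0] < cell.x1
                and cell.y0 <= c.centroid_map[1] < cell.y1
            )
            assert out.at[idx, "n_algarrobo_alive"] == n
        # each centroid in exactly one cell
        assert out["n_algarrobo_alive"].sum() == 60

    def test_crown_cover_conserved_under_clipping(self):
        rng = np.random.default_rng(4)
        cells = make_fishnet((0, 0, 100, 100), 50)
        crowns = [
            FakeCrown(rng.uniform(10, 90), rng.uniform(10, 90), "sapote", radius=6.0)
            for _ in range(15)
        ]  # several straddle cell boundaries
        out = summarize_cells(ClassifiedMap(crowns=crowns), cells)
        total_area = sum(c.polygon.area for c in crowns)
        assert out["crown_cover_m2"].sum() == pytest.approx(total_area, rel=1e-6)

    def test_pct_dead_arithmetic_and_nan(self):
        cells = make_fishnet((0, 0, 100, 50), 50)
        crowns = (
            [FakeCrown(25, 25, "algarrobo_alive") for _ in range(3)]
            + [FakeCrown(30, 30, "algarrobo_dead")]
        )
        out = summarize_cells(ClassifiedMap(crowns=crowns), cells)
        assert out.iloc[0]["pct_dead_algarrobo"] == pytest.approx(25.0)
        assert np.isnan(out.iloc[1]["pct_dead_algarrobo"])  # no Algarrobo there


class TestDensitySummary:
    def test_published_densities_and_composition(self):
        dens = density_summary(rs.PUBLISHED_ADJUSTED, rs.SURVEY_AREA_HA, rs.RAW_MAP_COUNTS)
        assert dens.at["total", "per_ha"] == pytest.approx(31.3)
        assert dens.at["sapote", "per_ha"] == pytest.approx(9.8)
        assert dens.at["algarrobo_alive", "per_ha"] == pytest.approx(14.0)
        assert dens.at["algarrobo_dead", "per_ha"] == pytest.approx(7.5)
        assert dens.at["sapote", "pct_trees"] == 31
        assert dens.at["algarrobo_dead", "pct_trees"] == 69
        assert dens.at["algarrobo_dead", "pct_dead"] == 35
        alg_ha = (rs.PUBLISHED_ADJUSTED["algarrobo_alive"]
                  + rs.PUBLISHED_ADJUSTED["algarrobo_dead"]) / rs.SURVEY_AREA_HA
        assert round(alg_ha, 1) == pytest.approx(21.5)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            density_summary(rs.PUBLISHED_ADJUSTED, 0.0)


def test_cells_geojson_export(tmp_path):
    import json

    from crownseg.io import write_cells

    cells = make_fishnet((0, 0, 100, 100), 50)
    out = summarize_cells(ClassifiedMap(crowns=[FakeCrown(25, 25, "sapote")]), cells)
    path = tmp_path / "cells.geojson"
    write_cells(out, path)
    fc = json.loads(path.read_text())
    assert len(fc["features"]) == 4
    props = {f["properties"]["cell_id"]: f["properties"] for f in fc["features"]}
    assert sum(p["n_sapote"] for p in props.values()) == 1
    assert all(p["pct_dead_algarrobo"] is None for p in props.values())
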