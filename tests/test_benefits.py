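import numpy as np
import pandas as pd
import pytest

from sepmap.benefits import (
    Benefit,
    BENEFITS,
    BenefitScoreTable,
    DEFAULT_SHRUB_WEIGHTS,
    compute_all_benefit_maps,
    compute_benefit_map,
    heat_map,
    homestead_distance_weights,
    shrubland_area_weights,
    voronoi_territories,
)
from sepmap.classes import PatchClass
from sepmap.grid import GridGeometry, Raster


def _grid(n=10, pixel=30.0):
    return GridGeometry(0.0, n * pixel, pixel, (n, n))


def _villages(coords):
    return pd.DataFrame(
        {
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "village_id": range(len(coords)),
        }
    )


class TestScoreTable:
    def test_default_semantics(self):
        t = BenefitScoreTable()
        for cls in ("water", "urban"):
            for b in BENEFITS:
                assert t.scores[(cls, b)] == 0
        for cls in ("bare_soil", "depression", "field", "forest", "homestead", "shrubland"):
            assert t.scores[(cls, Benefit.SAVING_INSURANCE)] > 0
        for cls in ("bare_soil", "shrubland", "forest"):
            assert t.scores[(cls, Benefit.ANNUAL_CROPS)] == 0

    def test_default_weight_flags(self):
        t = BenefitScoreTable()
        assert t.is_distance_weighted(int(PatchClass.FIELD), Benefit.INCOME)
        assert not t.is_distance_weighted(
            int(PatchClass.FIELD), Benefit.SAVING_INSURANCE
        )
        assert t.is_area_weighted(int(PatchClass.SHRUBLAND), Benefit.SAVING_INSURANCE)
        assert not t.is_area_weighted(int(PatchClass.FIELD), Benefit.SAVING_INSURANCE)

    def test_nonzero_land_cover_score_rejected(self):
        scores = {(c.label, b): 0.0 for c in PatchClass for b in BENEFITS}
        scores[("water", Benefit.INCOME)] = 1.0
        with pytest.raises(ValueError, match="water"):
            BenefitScoreTable(scores=scores)


class TestVoronoi:
    def test_single_village_gets_extent(self):
        grid = _grid()
        terr = voronoi_territories(_villages([(100, 100)]), grid)
        assert terr.polygons[0].equals(grid.extent_polygon)

    def test_two_villages_bisector(self):
        # villages at equal y, x = 60 and 240 on a 300 m square: split at x = 150
        grid = _grid(10)
        terr = voronoi_territories(_villages([(60, 150), (240, 150)]), grid)
        assert terr.polygons[0].area == pytest.approx(150 * 300)
        assert terr.polygons[1].area == pytest.approx(150 * 300)
        assert terr.polygons[0].bounds[2] == pytest.approx(150)  # xmax of left cell

    def test_partition_and_membership(self):
        rng = np.random.default_rng(5)
        grid = _grid(20)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            coords = [
                (rng.uniform(10, 590), rng.uniform(10, 590)) for _ in range(n)
            ]
            villages = _villages(coords)
            terr = voronoi_territories(villages, grid)
            assert terr.total_area == pytest.approx(
                grid.extent_polygon.area, rel=1e-6
            )
            from shapely.geometry import Point

            for _, row in villages.iterrows():
                assert terr.polygons[int(row["village_id"])].contains(
                    Point(row["x"], row["y"])
                )

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            voronoi_territories(_villages([(10, 10), (10, 10)]), _grid())


class TestDistanceWeights:
    def _mask(self, grid, rowcols):
        m = np.zeros(grid.shape, dtype=bool)
        for r, c in rowcols:
            m[r, c] = True
        return Raster(m, grid)

    def test_zone_weights(self):
        grid = _grid(40, pixel=30.0)
        w = homestead_distance_weights(
            self._mask(grid, [(0, 0)]), n_zones=5, zone_width_m=100.0
        ).raster.data
        assert w[0, 0] == 1.2  # inside a homestead
        assert w[0, 39] == 0.8  # far beyond the outermost zone
        # distance 210 m -> zone 2 of 5 -> midpoint weight 1.0
        assert w[0, 7] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        grid = _grid(5)
        with pytest.raises(ValueError, match="empty"):
            homestead_distance_weights(self._mask(grid, []))

    def test_bounds_for_random_configs(self):
        rng = np.random.default_rng(9)
        grid = _grid(15)
        for _ in range(20):
            mask = self._mask(
                grid, [(int(rng.integers(15)), int(rng.integers(15)))]
            )
            w = homestead_distance_weights(
                mask,
                n_zones=int(rng.integers(2, 8)),
                zone_width_m=float(rng.uniform(50, 600)),
            ).raster.data
            assert w.min() >= 0.8 and w.max() <= 1.2


class TestShrublandAreaWeights:
    def _patch_map(self, grid, shrub_fraction, rng):
        data = np.full(grid.shape, int(PatchClass.FIELD), dtype=np.int16)
        n = data.size
        idx = rng.choice(n, size=int(shrub_fraction * n), replace=False)
        data.flat[idx] = int(PatchClass.SHRUBLAND)
        return Raster(data, grid, nodata=0)

    def test_zero_shrubland_gets_lowest_category(self):
        grid = _grid(10)
        pm = Raster(np.full(grid.shape, int(PatchClass.FIELD), np.int16), grid, 0)
        terr = voronoi_territories(_villages([(150, 150)]), grid)
        w = shrubland_area_weights(pm, terr)
        assert np.all(w.raster.data == DEFAULT_SHRUB_WEIGHTS[0])
        assert terr.shrubland_fraction[0] == 0.0

    def test_mid_range_fraction_peaks(self):
        rng = np.random.default_rng(2)
        grid = _grid(20)
        pm = self._patch_map(grid, 0.18, rng)  # between 0.10 and 0.25
        terr = voronoi_territories(_villages([(300, 300)]), grid)
        w = shrubland_area_weights(pm, terr)
        assert np.all(w.raster.data == 1.2)

    def test_same_category_same_weight(self):
        rng = np.random.default_rng(3)
        grid = _grid(20)
        pm = self._patch_map(grid, 0.15, rng)
        terr = voronoi_territories(_villages([(100, 300), (500, 300)]), grid)
        w = shrubland_area_weights(pm, terr)
        f = terr.shrubland_fraction
        # both territories drawn from the same uniform scatter: same category
        cats = [
            np.searchsorted([0.02, 0.10, 0.25, 0.40], f[v], side="right")
            for v in (0, 1)
        ]
        if cats[0] == cats[1]:
            assert len(np.unique(w.raster.data)) == 1

    def test_invalid_schedules_rejected(self):
        grid = _grid(5)
        pm = Raster(np.full(grid.shape, 3, np.int16), grid, 0)
        terr = voronoi_territories(_villages([(75, 75)]), grid)
        with pytest.raises(ValueError):
            shrubland_area_weights(pm, terr, breakpoints=(0.1, 0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            shrubland_area_weights(pm, terr, weights=(0.5, 1.0, 1.2, 1.1, 0.9))


class TestBenefitMaps:
    def _setting(self, n=6):
        grid = _grid(n)
        data = np.full(grid.shape, int(PatchClass.FIELD), np.int16)
        data[0, 0] = int(PatchClass.HOMESTEAD)
        data[n - 1, n - 1] = int(PatchClass.WATER)
        pm = Raster(data, grid, nodata=0)
        dist_w = homestead_distance_weights(
            Raster(data == int(PatchClass.HOMESTEAD), grid), zone_width_m=100.0
        )
        terr = voronoi_territories(_villages([(40, grid.extent[3] - 40)]), grid)
        area_w = shrubland_area_weights(pm, terr)
        return grid, pm, dist_w, area_w

    def test_distance_weighted_field_income(self):
        grid, pm, dist_w, area_w = self._setting()
        table = BenefitScoreTable()
        table.scores[("field", Benefit.INCOME)] = 4.0
        out = compute_benefit_map(pm, table, dist_w, area_w, Benefit.INCOME)
        # field pixel adjacent to the homestead: nearest zone, weight 1.2
        assert out.data[0, 1] == pytest.approx(4.0 * 1.2)

    def test_saving_insurance_ignores_distance(self):
        grid, pm, dist_w, area_w = self._setting()
        table = BenefitScoreTable()
        out = compute_benefit_map(pm, table, dist_w, area_w, Benefit.SAVING_INSURANCE)
        field = pm.data == int(PatchClass.FIELD)
        vals = np.unique(out.data[field])
        assert len(vals) == 1  # same score at every distance zone

    def test_water_scores_zero(self):
        grid, pm, dist_w, area_w = self._setting()
        out = compute_benefit_map(
            pm, BenefitScoreTable(), dist_w, area_w, Benefit.INCOME
        )
        assert out.data[-1, -1] == 0.0

    def test_missing_score_entry_rejected(self):
        grid, pm, dist_w, area_w = self._setting()
        table = BenefitScoreTable()
        del table.scores[("field", Benefit.INCOME)]
        with pytest.raises(KeyError, match="field"):
            compute_benefit_map(pm, table, dist_w, area_w, Benefit.INCOME)

    def test_monotone_distance_decay(self):
        grid = _grid(40)
        data = np.full(grid.shape, int(PatchClass.FIELD), np.int16)
        data[0, 0] = int(PatchClass.HOMESTEAD)
        pm = Raster(data, grid, nodata=0)
        dist_w = homestead_distance_weights(
            Raster(data == int(PatchClass.HOMESTEAD), grid), zone_width_m=150.0
        )
        terr = voronoi_territories(_villages([(20, grid.extent[3] - 20)]), grid)
        area_w = shrubland_area_weights(pm, terr)
        out = compute_benefit_map(
            pm, BenefitScoreTable(), dist_w, area_w, Benefit.INCOME
        )
        profile = out.data[0, 1:]  # increasing distance along the row
        assert np.all(np.diff(profile) <= 1e-12)

    def test_zero_score_zero_everywhere(self):
        grid, pm, dist_w, area_w = self._setting()
        out = compute_benefit_map(
            pm, BenefitScoreTable(), dist_w, area_w, Benefit.ANNUAL_CROPS
        )
        # shrubland scores 0 for annual crops -> exact zero despite weights
        pm.data[2, 2] = int(PatchClass.SHRUBLAND)
        out2 = compute_benefit_map(
            pm, BenefitScoreTable(), dist_w, area_w, Benefit.ANNUAL_CROPS
        )
        assert out2.data[2, 2] == 0.0


class TestHeatMap:
    def test_sum_of_ones(self, small_grid):
        maps = [Raster(np.ones(small_grid.shape), small_grid, np.nan) for _ in range(5)]
        assert np.all(heat_map(maps).data == 5.0)

    def test_all_zero(self, small_grid):
        maps = [Raster(np.zeros(small_grid.shape), small_grid, np.nan) for _ in range(5)]
        assert np.all(heat_map(maps).data == 0.0)

    def test_wrong_count_rejected(self, small_grid):
        maps = [Raster(np.ones(small_grid.shape), small_grid, np.nan) for _ in range(4)]
        with pytest.raises(ValueError, match="5"):
            heat_map(maps)

    def test_nodata_propagates(self, small_grid):
        maps = [Raster(np.ones(small_grid.shape), small_grid, np.nan) for _ in range(5)]
        maps[2].data[3, 3] = np.nan
        out = heat_map(maps)
        assert np.isnan(out.data[3, 3]) and out.data[0, 0] == 5.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        grid = GridGeometry(0, 8 * 30.0, 30.0, (8, 8))
        maps = [Raster(rng.uniform(0, 5, (8, 8)), grid, np.nan) for _ in range(5)]
        out = heat_map(maps).data
        for r in range(8):
            for c in range(8):
                expected = sum(m.data[r, c] for m in maps)
                assert out[r, c] == expected  # exact summation order

    def test_conservation_with_real_benefit_maps(self):
        grid = _grid(12)
        rng = np.random.default_rng(11)
        data = rng.choice(
            [int(c) for c in PatchClass], size=grid.shape
        ).astype(np.int16)
        data[0, 0] = int(PatchClass.HOMESTEAD)
        pm = Raster(data, grid, nodata=0)
        dist_w = homestead_distance_weights(
            Raster(data == int(PatchClass.HOMESTEAD), grid), zone_width_m=120.0
        )
        terr = voronoi_territories(_villages([(180, 180)]), grid)
        area_w = shrubland_area_weights(pm, terr)
        maps = compute_all_benefit_maps(pm, BenefitScoreTable(), dist_w, area_w)
        total = heat_map(maps).data
        manual = sum(m.data for m in maps.values())
        np.testing.assert_array_equal(total, manual)
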