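"""Geographic distances, supercover transects, and landscape permutation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from landgraph import landscape, synthetic
from landgraph.core import DegenerateInputError, spawn_rng
from landgraph.landscape import RasterLayer
from landgraph.synthetic import SyntheticScenario


def locales_df(points):
    return pd.DataFrame(
        [{"locale_id": f"L{i:02d}", "x": x, "y": y} for i, (x, y) in enumerate(points)]
    )


def flat_raster(value=1.0, shape=(20, 30), **kw):
    return RasterLayer(
        grid=np.full(shape, float(value)), x_origin=0.0,
        y_origin=float(shape[0]), pixel_size=1.0, **kw,
    )


class TestGeographicDistance:
    def test_three_four_five_triangle(self):
        loc = locales_df([(0, 0), (3, 4)])
        m = landscape.geographic_distance_matrix(loc)
        assert m.get("L00", "L01") == pytest.approx(5.0)

    def test_haversine_one_degree_on_equator(self):
        loc = locales_df([(0, 0), (1, 0)])
        m = landscape.geographic_distance_matrix(loc, mode="haversine")
        # great-circle closed form: 2πR/360 with R = 6371 km
        assert m.get("L00", "L01") == pytest.approx(2 * np.pi * 6371 / 360, rel=1e-6)

    def test_identical_points_warn_distance_zero(self):
        loc = locales_df([(1, 1), (1, 1)])
        with pytest.warns(UserWarning, match="identical"):
            m = landscape.geographic_distance_matrix(loc)
        assert m.get("L00", "L01") == 0.0


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path):
        sc = SyntheticScenario(raster_extent=(8, 11), seed=2)
        ras = synthetic.make_landscape(sc, "gradient", direction="south", low=1, high=9)
        ras.write_ascii_grid(tmp_path / "r.asc")
        back = landscape.read_ascii_grid(tmp_path / "r.asc")
        np.testing.assert_allclose(back.grid, ras.grid)
        assert back.x_origin == ras.x_origin
        assert back.y_origin == ras.y_origin
        assert back.pixel_size == ras.pixel_size

    def test_categorical_codes_validated(self):
        with pytest.raises(ValueError, match="codes"):
            RasterLayer(
                grid=np.array([[0.5]]), x_origin=0, y_origin=1,
                pixel_size=1.0, kind="categorical",
            )


class TestTransects:
    def test_degenerate_point_transect(self):
        ras = flat_raster(7.0)
        t = landscape.extract_transect(ras, (3.5, 3.5), (3.5, 3.5))
        assert t.values.tolist() == [7.0]
        assert t.n_pixels == 1

    def test_constant_raster_values(self):
        ras = flat_raster(4.0)
        t = landscape.extract_transect(ras, (0.5, 0.5), (29.5, 19.5))
        assert (t.values == 4.0).all()
        assert t.n_pixels >= 30  # touches at least one pixel per column

    def test_gradient_transect_is_arithmetic_progression(self):
        sc = SyntheticScenario(raster_extent=(4, 100))
        ras = synthetic.make_landscape(sc, "gradient", direction="east", low=0, high=100)
        t = landscape.extract_transect(ras, (10.5, 2.0), (90.5, 2.0))
        diffs = np.diff(t.values)
        assert np.allclose(diffs, diffs[0])
        # mean equals the midpoint value within half a pixel's increment
        mid = ras.grid[2, 50]
        assert abs(t.values.mean() - mid) <= 100 / 99

    def test_supercover_symmetry(self, rng):
        """transect(a, b) visits exactly the reversed pixel set of transect(b, a)."""
        ras = flat_raster(1.0, shape=(25, 25))
        for _ in range(50):
            a = tuple(rng.uniform(0.1, 24.9, 2))
            b = tuple(rng.uniform(0.1, 24.9, 2))
            t_ab = landscape.extract_transect(ras, a, b)
            t_ba = landscape.extract_transect(ras, b, a)
            assert t_ab.cells == t_ba.cells[::-1]

    def test_outside_extent_rejected(self):
        ras = flat_raster()
        with pytest.raises(ValueError, match="outside"):
            landscape.extract_transect(ras, (-5, 5), (5, 5))

    def test_all_nodata_transect_is_an_error(self):
        ras = flat_raster(-9999.0)
        with pytest.raises(DegenerateInputError, match="nodata"):
            landscape.extract_transect(ras, (1.5, 1.5), (5.5, 5.5))


class TestEdgeSummaries:
    def test_constant_raster_zero_variance(self):
        ras = flat_raster(3.0)
        loc = locales_df([(1, 1), (10, 15), (25, 5)])
        pairs = [("L00", "L01"), ("L01", "L02")]
        df = landscape.edge_resistance_summary(ras, pairs, loc)
        assert (df["mean"] == 3.0).all()
        assert (df["variance"] == 0.0).all()

    def test_parallel_gradient_transects(self):
        """Equal-length transects at different gradient offsets differ in mean
        but share the same variance."""
        sc = SyntheticScenario(raster_extent=(40, 60))
        ras = synthetic.make_landscape(sc, "gradient", direction="east", low=0, high=59)
        loc = locales_df([(5.5, 5.5), (45.5, 5.5), (15.5, 30.5), (55.5, 30.5)])
        df = landscape.edge_resistance_summary(
            ras, [("L00", "L01"), ("L02", "L03")], loc
        )
        assert df["mean"][1] - df["mean"][0] == pytest.approx(10.0, abs=1e-9)
        assert df["variance"][0] == pytest.approx(df["variance"][1], abs=1e-9)

    def test_nodata_pixels_masked(self):
        grid = np.full((10, 30), 2.0)
        grid[:, 10:20] = -9999.0  # middle third nodata
        ras = RasterLayer(grid=grid, x_origin=0, y_origin=10, pixel_size=1.0)
        loc = locales_df([(0.5, 5.5), (29.5, 5.5)])
        df = landscape.edge_resistance_summary(ras, [("L00", "L01")], loc)
        assert df["mean"][0] == 2.0
        assert df["n_pixels"][0] == 20

    def test_fully_nodata_edge_flagged(self):
        ras = flat_raster(-9999.0)
        loc = locales_df([(1.5, 1.5), (5.5, 5.5)])
        with pytest.warns(UserWarning, match="nodata"):
            df = landscape.edge_resistance_summary(ras, [("L00", "L01")], loc)
        assert bool(df["missing"][0])


class TestCategoricalProfile:
    def test_single_class_proportion_one(self):
        ras = flat_raster(2.0, kind="categorical", class_table={2: "thicket"})
        loc = locales_df([(1, 1), (20, 15)])
        df = landscape.categorical_edge_profile(ras, [("L00", "L01")], loc)
        assert df["class_2"][0] == 1.0

    def test_half_plane_split_is_half(self):
        grid = np.zeros((20, 40))
        grid[:, 20:] = 1.0
        ras = RasterLayer(
            grid=grid, x_origin=0, y_origin=20, pixel_size=1.0,
            kind="categorical", class_table={0: "a", 1: "b"},
        )
        loc = locales_df([(0.5, 10.2), (39.5, 10.2)])
        df = landscape.categorical_edge_profile(ras, [("L00", "L01")], loc)
        assert df["class_0"][0] == pytest.approx(0.5, abs=1 / 40)
        assert df["class_0"][0] + df["class_1"][0] == pytest.approx(1.0)

    def test_unvisited_class_aggregates_to_zero(self):
        grid = np.zeros((10, 10))
        grid[9, 9] = 3.0  # class present in raster, far from the transect
        ras = RasterLayer(
            grid=grid, x_origin=0, y_origin=10, pixel_size=1.0,
            kind="categorical", class_table={0: "a", 3: "d"},
        )
        loc = locales_df([(0.5, 9.5), (5.5, 9.5)])
        df = landscape.categorical_edge_profile(ras, [("L00", "L01")], loc)
        assert landscape.aggregate_statistic(df, "category:3") == 0.0


class TestLandscapePermutation:
    def _random_graph(self, loc, m, seed):
        ids = list(loc["locale_id"])
        g = nx.gnm_random_graph(len(ids), m, seed=seed)
        g = nx.relabel_nodes(g, dict(enumerate(ids)))
        nx.set_edge_attributes(g, 1.0, "weight")
        return g

    def test_constant_raster_gives_p_one(self):
        ras = flat_raster(5.0, shape=(30, 30))
        sc = SyntheticScenario(n_locales=10, raster_extent=(30, 30), seed=3)
        loc = synthetic.make_locales(sc)
        g = self._random_graph(loc, 20, seed=3)
        res = landscape.landscape_permutation_test(
            g, ras, loc, statistic="mean", n_perm=40, seed=4
        )
        assert res.p_value == 1.0
        assert np.allclose(res.null_values, res.observed)

    def test_deterministic_under_fixed_seed(self):
        sc = SyntheticScenario(n_locales=10, raster_extent=(30, 40), seed=5)
        ras = synthetic.make_landscape(sc, "gradient", direction="east", low=0, high=10)
        loc = synthetic.make_locales(sc)
        g = self._random_graph(loc, 20, seed=5)
        r1 = landscape.landscape_permutation_test(g, ras, loc, n_perm=30, seed=6)
        r2 = landscape.landscape_permutation_test(g, ras, loc, n_perm=30, seed=6)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_too_few_edges_rejected(self):
        loc = locales_df([(1, 1), (5, 5), (9, 9)])
        g = nx.Graph()
        g.add_nodes_from(loc["locale_id"])
        g.add_edge("L00", "L01", weight=1.0)
        with pytest.raises(DegenerateInputError):
            landscape.landscape_permutation_test(g, flat_raster(), loc, n_perm=5)
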