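import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from walkcity.data import load_city_access_benchmarks, load_city_threshold_benchmarks
from walkcity.region_grid import RegionBoundary, build_hex_grid, build_square_grid
from walkcity.summarise import (
    aggregate_to_hex,
    city_percentages,
    export_outputs,
    group_summary,
    hex_populations,
    hex_pos_access,
)


def points_frame(hex_ids, walkability, pos_large=None):
    n = len(hex_ids)
    return pd.DataFrame(
        {
            "point_id": np.arange(n),
            "hex_id": hex_ids,
            "pop_density": 1000.0,
            "int_density": 50.0,
            "daily_living": 2.0,
            "walkability_within": walkability,
            "access_pos_large_entry": pos_large if pos_large is not None else np.zeros(n),
        }
    )


class TestAggregateToHex:
    def test_mean_of_point_values(self):
        pts = points_frame([5, 5], [-1.0, 1.0])
        hexes = pd.DataFrame({"hex_id": [5], "geometry": [box(0, 0, 1, 1)]})
        out = aggregate_to_hex(pts, hexes)
        assert np.isclose(out["walkability_within"].iloc[0], 0.0)
        assert out["n_points"].iloc[0] == 2

    def test_single_point_hex_equals_point(self):
        pts = points_frame([3], [0.7])
        hexes = pd.DataFrame({"hex_id": [3], "geometry": [box(0, 0, 1, 1)]})
        out = aggregate_to_hex(pts, hexes)
        assert np.isclose(out["walkability_within"].iloc[0], 0.7)

    def test_permutation_invariance(self):
        pts = points_frame([1, 2, 1, 2, 1], [0.1, 0.2, 0.3, 0.4, 0.5])
        hexes = pd.DataFrame({"hex_id": [1, 2], "geometry": [box(0, 0, 1, 1)] * 2})
        a = aggregate_to_hex(pts, hexes)
        b = aggregate_to_hex(pts.sample(frac=1.0, random_state=7), hexes)
        pd.testing.assert_frame_equal(
            a.sort_values("hex_id").reset_index(drop=True),
            b.sort_values("hex_id").reset_index(drop=True),
            check_like=True,
        )

    def test_empty_hexes_omitted(self):
        pts = points_frame([1], [0.0])
        hexes = pd.DataFrame({"hex_id": [1, 2], "geometry": [box(0, 0, 1, 1)] * 2})
        out = aggregate_to_hex(pts, hexes)
        assert list(out["hex_id"]) == [1]


class TestHexPosAccess:
    @pytest.mark.parametrize("mean,want", [(0.75, 1), (0.5, 1), (0.0, 0), (0.49, 0)])
    def test_at_least_half_rule(self, mean, want):
        assert hex_pos_access([mean])[0] == want


class TestHexPopulations:
    def test_population_conserved_under_areal_assignment(self):
        region = RegionBoundary(box(0, 0, 1000, 1000))
        grid = build_square_grid(region)
        rng = np.random.default_rng(3)
        grid["population"] = rng.uniform(0, 500, len(grid))
        hexes = build_hex_grid(region)
        pops = hex_populations(hexes, grid)
        assert np.isclose(pops.sum(), grid["population"].sum(), rtol=1e-9)


class TestCityPercentages:
    def hex_summary(self, pops, access):
        return pd.DataFrame(
            {
                "hex_id": np.arange(len(pops)),
                "population": pops,
                "access_food_market": access,
                "pop_density": 5000.0,
                "int_density": 95.0,
            }
        )

    def test_population_weighted_mean(self):
        hs = self.hex_summary([100.0, 300.0], [1.0, 0.0])
        out = city_percentages(hs)
        assert np.isclose(out["pct_food_market"], 25.0)

    def test_scenario_exposure_all_meet(self):
        hs = self.hex_summary([10.0, 10.0], [0.0, 0.0])
        out = city_percentages(hs)
        assert out["pct_pop_density_A"] == 100.0  # 5000 >= 4790
        assert out["pct_pop_density_B"] == 0.0  # 5000 < 5677

    def test_invariant_under_uniform_population_scaling(self):
        hs = self.hex_summary([50.0, 150.0, 200.0], [1.0, 0.5, 0.0])
        a = city_percentages(hs)
        hs2 = hs.assign(population=hs["population"] * 12.5)
        b = city_percentages(hs2)
        assert np.isclose(a["pct_food_market"], b["pct_food_market"])

    def test_zero_population_error(self):
        with pytest.raises(ValueError):
            city_percentages(self.hex_summary([0.0], [1.0]))

    def test_missing_class_propagates_nan(self):
        hs = self.hex_summary([10.0], [1.0])
        out = city_percentages(hs)
        assert np.isnan(out["pct_pt_stop_30min"])


class TestGroupSummary:
    def test_benchmark_middle_income_food_mean(self):
        cities = load_city_access_benchmarks()
        groups = group_summary(cities, grouping="income_group")
        mid = groups[groups["group"] == "middle"].iloc[0]
        assert round(mid["pct_food_market_mean"], 1) == 25.3

    def test_benchmark_total_food_mean(self):
        cities = load_city_access_benchmarks()
        groups = group_summary(cities, grouping="income_group")
        total = groups[groups["group"] == "Total"].iloc[0]
        assert round(total["pct_food_market_mean"], 1) == 36.4

    def test_single_city_group(self):
        cities = pd.DataFrame({"income_group": ["solo"], "pct_food_market": [42.0]})
        groups = group_summary(cities, grouping="income_group")
        solo = groups[groups["group"] == "solo"].iloc[0]
        assert solo["pct_food_market_mean"] == 42.0
        assert solo["pct_food_market_sd"] == 0.0

    def test_missing_values_excluded_per_indicator(self):
        cities = load_city_access_benchmarks()
        groups = group_summary(cities, grouping="income_group")
        total = groups[groups["group"] == "Total"].iloc[0]
        # five cities lack transit-schedule data; PM2.5 missing for one
        assert round(total["pm25_transport_tpa_mean"], 1) == 655.3

    def test_group_mean_within_member_range(self):
        cities = load_city_access_benchmarks()
        groups = group_summary(cities, grouping="income_group")
        for g in ("middle", "high"):
            sub = cities[cities["income_group"] == g]["pct_convenience"]
            row = groups[groups["group"] == g].iloc[0]
            assert sub.min() <= row["pct_convenience_mean"] <= sub.max()


class TestBenchmarkTables:
    def test_access_table_shape_and_missing_pattern(self):
        cities = load_city_access_benchmarks()
        assert len(cities) == 25
        assert cities["income_group"].value_counts().to_dict() == {"high": 19, "middle": 6}
        # cities without machine-readable schedules have no service-class values
        no_gtfs = cities[cities["pct_pt_stop_30min"].isna()]["city"]
        assert set(no_gtfs) == {"Maiduguri", "Graz", "Ghent", "Olomouc", "Vic"}
        assert cities["pm25_transport_tpa"].isna().sum() == 1

    def test_threshold_table_orderings(self):
        t = load_city_threshold_benchmarks()
        assert len(t) == 25
        # scenario B exposure never exceeds scenario A, row-wise
        assert (t["pct_pop_density_B"] <= t["pct_pop_density_A"]).all()
        assert (t["pct_int_density_B"] <= t["pct_int_density_A"]).all()

    def test_access_orderings_across_cities(self):
        cities = load_city_access_benchmarks()
        m = cities.dropna(subset=["pct_pt_stop_30min"])
        assert (m["pct_pt_stop_20min"] <= m["pct_pt_stop_30min"]).all()
        assert (m["pct_pt_stop_30min"] <= m["pct_pt_stop_any"]).all()
        assert (cities["pct_pos_large_entry"] <= cities["pct_pos_any_entry"]).all()


class TestCompareCities:
    def test_between_city_walkability_centred_on_pooled_average(self):
        import warnings

        from walkcity.pipeline import compare_cities, run_synthetic
        from walkcity.synthetic_city import CitySpec

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            runs = [
                run_synthetic(
                    CitySpec(seed=s, extent_m=1000.0, pop_total=5000, n_stops=0),
                    name=f"city{s}",
                )
                for s in (1, 2)
            ]
        out = compare_cities(runs)
        pooled = out["pooled_hexes"]
        # zero marks the all-cities average by construction
        assert abs(pooled["walkability_between"].mean()) < 1e-9
        assert set(out["cities"]["city"]) == {"city1", "city2"}
        assert "Total" in set(out["groups"]["group"])


class TestExport:
    def test_reexport_is_deterministic(self, tmp_path):
        hs = pd.DataFrame({"hex_id": [0, 1], "population": [1.0, 2.0], "pop_density": [1.0, 2.0]})
        city = {"city": "t", "pct_food_market": 12.345678}
        a = export_outputs(tmp_path / "a", hex_summary=hs, city=city, manifest={"seed": 1})
        b = export_outputs(tmp_path / "b", hex_summary=hs, city=city, manifest={"seed": 1})
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
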