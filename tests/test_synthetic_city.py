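import numpy as np
import pandas as pd
import pytest

from walkcity.synthetic_city import (
    CitySpec,
    InvalidSpecError,
    PosSpec,
    generate_city,
    generate_destinations,
    generate_gtfs,
    generate_planted_access_city,
    generate_population_grid,
    generate_street_network,
    region_for,
)
from walkcity.transit import parse_gtfs, representative_weekday, stop_headways

import networkx as nx


class TestStreetNetwork:
    def test_grid_layout_is_a_lattice(self, lattice_spec, lattice_net):
        # 1000 m extent at 250 m blocks: 5x5 nodes, 40 edges of 250 m
        assert len(lattice_net.nodes) == 25
        assert len(lattice_net.edges) == 40
        assert np.allclose(lattice_net.edges["length_m"], 250.0)

    def test_identical_seed_gives_byte_identical_tables(self):
        spec = CitySpec(seed=7, layout="organic")
        a, b = generate_street_network(spec), generate_street_network(spec)
        assert a.nodes.to_csv() == b.nodes.to_csv()
        assert a.edges.drop(columns="geometry").to_csv() == b.edges.drop(columns="geometry").to_csv()

    def test_organic_layout_stays_connected(self):
        spec = CitySpec(seed=5, layout="organic", edge_removal_frac=0.2)
        net = generate_street_network(spec)
        assert nx.is_connected(net.graph)
        # and some edges were actually removed relative to the full lattice
        full = generate_street_network(CitySpec(seed=5, layout="grid"))
        assert len(net.edges) < len(full.edges)

    def test_organic_noise_bounded(self):
        spec = CitySpec(seed=2, layout="organic", edge_removal_frac=0.0)
        net = generate_street_network(spec)
        ref = generate_street_network(CitySpec(seed=2, layout="grid"))
        shift = np.hypot(net.nodes.x - ref.nodes.x, net.nodes.y - ref.nodes.y)
        assert shift.max() <= 0.3 * spec.block_m + 1e-9

    def test_too_few_blocks_rejected(self):
        with pytest.raises(InvalidSpecError):
            CitySpec(extent_m=700, block_m=250)


class TestPopulationGrid:
    def test_population_conserved(self, lattice_spec, lattice_region):
        grid = generate_population_grid(lattice_spec, lattice_region)
        assert grid["population"].sum() == lattice_spec.pop_total

    def test_zero_gradient_gives_uniform_expected_weights(self):
        spec = CitySpec(seed=1, pop_gradient=0.0, pop_total=400_000, extent_m=2000)
        grid = generate_population_grid(spec, region_for(spec))
        # multinomial with equal weights: all cells near total/n_cells
        expected = spec.pop_total / len(grid)
        assert abs(grid["population"].mean() - expected) < 1e-9
        assert grid["population"].std() < 0.05 * expected

    def test_positive_gradient_concentrates_centre(self):
        spec = CitySpec(seed=1, pop_gradient=3.0, pop_total=50_000, extent_m=3000)
        region = region_for(spec)
        grid = generate_population_grid(spec, region)
        cx = cy = spec.extent_m / 2
        r = np.hypot(
            [g.centroid.x - cx for g in grid.geometry],
            [g.centroid.y - cy for g in grid.geometry],
        )
        inner = grid.population[r <= np.quantile(r, 0.25)].mean()
        outer = grid.population[r >= np.quantile(r, 0.75)].mean()
        assert inner > outer


class TestDestinations:
    def test_requested_counts(self, lattice_net):
        spec = CitySpec(seed=4, extent_m=1000, n_food=10, n_convenience=3, n_stops=2)
        layers = generate_destinations(spec, lattice_net)
        assert len(layers["food_market"]) == 10
        assert len(layers["convenience"]) == 3
        assert len(layers["pt_stop"]) == 2

    def test_pos_area_within_tolerance(self, lattice_net):
        spec = CitySpec(seed=4, extent_m=1000, pos_polygons=(PosSpec(1.5),))
        layers = generate_destinations(spec, lattice_net)
        area_ha = layers["pos"]["geometry"].iloc[0].area / 10_000
        assert 1.425 <= area_ha <= 1.575

    def test_destinations_snap_within_20m(self, lattice_net):
        import shapely

        spec = CitySpec(seed=9, extent_m=1000, n_food=20)
        layers = generate_destinations(spec, lattice_net)
        edge_geoms = np.asarray(lattice_net.edges["geometry"], dtype=object)
        for r in layers["food_market"].itertuples():
            d = shapely.distance(edge_geoms, shapely.Point(r.x, r.y)).min()
            assert d <= 20.0

    def test_clustering_reduces_nearest_neighbour_distance(self, lattice_net):
        def mean_nn(df):
            xy = df[["x", "y"]].to_numpy()
            d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        clustered = generate_destinations(
            CitySpec(seed=11, extent_m=1000, n_food=20, cluster_factor=1.0), lattice_net
        )["food_market"]
        dispersed = generate_destinations(
            CitySpec(seed=11, extent_m=1000, n_food=20, cluster_factor=0.0), lattice_net
        )["food_market"]
        assert mean_nn(clustered) < mean_nn(dispersed)


class TestGTFS:
    def test_departures_per_stop(self, tmp_path, lattice_net):
        spec = CitySpec(seed=2, extent_m=1000, n_stops=4, transit_headway_min=20)
        stops = generate_destinations(spec, lattice_net)["pt_stop"]
        gtfs = generate_gtfs(spec, stops, tmp_path / "gtfs")
        st = pd.read_csv(gtfs / "stop_times.txt")
        # 06:00-22:00 inclusive at 20 min: 49 departures at every stop
        assert (st.groupby("stop_id").size() == 49).all()

    def test_weekday_only_calendar(self, tmp_path, lattice_net):
        spec = CitySpec(seed=2, extent_m=1000, n_stops=2)
        stops = generate_destinations(spec, lattice_net)["pt_stop"]
        gtfs = generate_gtfs(spec, stops, tmp_path / "gtfs")
        cal = pd.read_csv(gtfs / "calendar.txt").iloc[0]
        assert all(cal[d] == 1 for d in ("monday", "tuesday", "wednesday", "thursday", "friday"))
        assert cal["saturday"] == 0 and cal["sunday"] == 0

    def test_round_trip_headway_estimate(self, tmp_path, lattice_net):
        spec = CitySpec(seed=2, extent_m=1000, n_stops=5, transit_headway_min=25)
        stops = generate_destinations(spec, lattice_net)["pt_stop"]
        gtfs = generate_gtfs(spec, stops, tmp_path / "gtfs")
        feed = parse_gtfs(gtfs, origin_lonlat=(0.0, 0.0))
        assert len(feed.stops) == 5
        _, services = representative_weekday(feed)
        hw = stop_headways(feed, services)
        assert np.allclose(hw["mean_headway_min"], 25.0)
        # and stop coordinates survive the projection round trip
        orig = stops.sort_values("dest_id")[["x", "y"]].to_numpy()
        back = feed.stops.sort_values("stop_id")[["x", "y"]].to_numpy()
        assert np.allclose(orig, back, atol=0.1)


class TestPlantedCity:
    @pytest.mark.parametrize("p", [0.0, 0.5, 1.0])
    def test_population_split_matches_fraction(self, p):
        city = generate_planted_access_city(p, extent_m=2000.0)
        assert city.true_fraction == p
        assert np.isclose(city.grid["population"].sum(), 10_000.0)
        if 0 < p < 1:
            west = city.grid["population"][city.grid["col"] <= 2].sum()
            assert np.isclose(west / 10_000.0, p)
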