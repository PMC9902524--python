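import numpy as np
import pandas as pd
import pytest

from walkcity.transit import (
    GTFSFeed,
    GTFSFormatError,
    parse_gtfs,
    parse_gtfs_time,
    representative_weekday,
    stop_headways,
    transit_stop_layers,
)


def make_feed(departures_by_stop, calendar_days=None, service_id="WK"):
    """Minimal in-memory feed: one trip per departure time per stop."""
    stops = pd.DataFrame(
        {
            "stop_id": list(departures_by_stop),
            "stop_lat": 0.0,
            "stop_lon": 0.0,
            "x": 0.0,
            "y": 0.0,
        }
    )
    st_rows, trip_rows = [], []
    k = 0
    for stop_id, times in departures_by_stop.items():
        for t in times:
            tid = f"t{k}"
            trip_rows.append({"route_id": "R", "service_id": service_id, "trip_id": tid})
            st_rows.append(
                {"trip_id": tid, "stop_id": stop_id, "departure_s": parse_gtfs_time(t), "stop_sequence": 1}
            )
            k += 1
    days = calendar_days or {"monday": 1, "tuesday": 1, "wednesday": 1, "thursday": 1, "friday": 1, "saturday": 0, "sunday": 0}
    calendar = pd.DataFrame([{"service_id": service_id, **days, "start_date": 20150105, "end_date": 20151231}])
    return GTFSFeed(stops=stops, trips=pd.DataFrame(trip_rows), stop_times=pd.DataFrame(st_rows), calendar=calendar)


class TestTimeParsing:
    def test_after_midnight_times_accepted(self):
        assert parse_gtfs_time("25:10:00") == 25 * 3600 + 600

    def test_bad_time_rejected(self):
        with pytest.raises(ValueError):
            parse_gtfs_time("8h30")

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(GTFSFormatError):
            parse_gtfs(tmp_path)


class TestRepresentativeWeekday:
    def test_uniform_service_picks_monday(self):
        feed = make_feed({"a": ["08:00:00", "09:00:00"]})
        day, services = representative_weekday(feed)
        assert day == "monday"
        assert services == {"WK"}

    def test_day_with_extra_trips_wins(self):
        base = make_feed({"a": ["08:00:00"]})
        wed = make_feed(
            {"a": ["08:00:00", "09:00:00", "10:00:00"]},
            calendar_days={"monday": 0, "tuesday": 0, "wednesday": 1, "thursday": 0, "friday": 0, "saturday": 0, "sunday": 0},
            service_id="WED",
        )
        feed = GTFSFeed(
            stops=base.stops,
            trips=pd.concat([base.trips, wed.trips], ignore_index=True),
            stop_times=pd.concat([base.stop_times, wed.stop_times], ignore_index=True),
            calendar=pd.concat([base.calendar, wed.calendar], ignore_index=True),
        )
        day, services = representative_weekday(feed)
        assert day == "wednesday"
        # every service active on the chosen day is selected
        assert services == {"WK", "WED"}

    def test_weekend_only_feed_empty(self):
        feed = make_feed(
            {"a": ["08:00:00"]},
            calendar_days={"monday": 0, "tuesday": 0, "wednesday": 0, "thursday": 0, "friday": 0, "saturday": 1, "sunday": 1},
        )
        with pytest.warns(UserWarning, match="no weekday service"):
            day, services = representative_weekday(feed)
        assert day is None and services == frozenset()


class TestStopHeadways:
    def test_mean_of_consecutive_gaps(self):
        feed = make_feed({"a": ["08:00:00", "08:20:00", "08:40:00"]})
        hw = stop_headways(feed, {"WK"})
        row = hw.iloc[0]
        assert np.isclose(row["mean_headway_min"], 20.0)
        assert row["class_20"] == 1 and row["class_30"] == 1

    def test_single_departure_undefined(self):
        feed = make_feed({"a": ["08:00:00"]})
        row = stop_headways(feed, {"WK"}).iloc[0]
        assert np.isnan(row["mean_headway_min"])
        assert row["class_30"] == 0 and row["class_20"] == 0

    def test_departures_outside_window_ignored(self):
        feed = make_feed({"a": ["05:00:00", "08:00:00", "08:30:00", "23:00:00"]})
        row = stop_headways(feed, {"WK"}).iloc[0]
        assert row["n_departures"] == 2
        assert np.isclose(row["mean_headway_min"], 30.0)
        assert row["class_30"] == 1 and row["class_20"] == 0

    def test_duplicated_schedule_under_new_route_invariant(self):
        feed = make_feed({"a": ["08:00:00", "08:25:00", "08:50:00"]})
        dup_trips = feed.trips.copy()
        dup_trips["trip_id"] = dup_trips["trip_id"] + "_dup"
        dup_trips["route_id"] = "R2"
        dup_st = feed.stop_times.copy()
        dup_st["trip_id"] = dup_st["trip_id"] + "_dup"
        doubled = GTFSFeed(
            stops=feed.stops,
            trips=pd.concat([feed.trips, dup_trips], ignore_index=True),
            stop_times=pd.concat([feed.stop_times, dup_st], ignore_index=True),
            calendar=feed.calendar,
        )
        a = stop_headways(feed, {"WK"})["mean_headway_min"].iloc[0]
        b = stop_headways(doubled, {"WK"})["mean_headway_min"].iloc[0]
        assert np.isclose(a, b)

    def test_class_nesting(self):
        feed = make_feed(
            {
                "fast": [f"{h:02d}:{m:02d}:00" for h in range(7, 19) for m in (0, 15, 30, 45)],
                "medium": [f"{h:02d}:00:00" for h in range(7, 19)] + [f"{h:02d}:25:00" for h in range(7, 19)],
                "slow": ["08:00:00", "12:00:00", "16:00:00"],
            }
        )
        hw = stop_headways(feed, {"WK"})
        assert (hw["class_20"] <= hw["class_30"]).all()
        layers = transit_stop_layers(feed, hw)
        ids_20 = set(layers["pt_stop_20min"]["stop_id"])
        ids_30 = set(layers["pt_stop_30min"]["stop_id"])
        ids_any = set(layers["pt_stop_any"]["stop_id"])
        assert ids_20 <= ids_30 <= ids_any

    def test_halving_generator_headway_halves_estimate(self, tmp_path, lattice_net):
        from walkcity.synthetic_city import CitySpec, generate_destinations, generate_gtfs

        means = {}
        for h in (10, 20):
            spec = CitySpec(seed=3, extent_m=1000, n_stops=3, transit_headway_min=h)
            stops = generate_destinations(spec, lattice_net)["pt_stop"]
            gtfs = generate_gtfs(spec, stops, tmp_path / f"gtfs{h}")
            feed = parse_gtfs(gtfs, origin_lonlat=(0.0, 0.0))
            _, services = representative_weekday(feed)
            means[h] = stop_headways(feed, services)["mean_headway_min"].mean()
        assert np.isclose(means[20], 2 * means[10], rtol=0.01)


class TestFrequenciesExpansion:
    def test_frequency_trips_expand_to_departures(self, tmp_path):
        from walkcity.transit import expand_frequencies

        feed = make_feed({"a": ["07:00:00"]})
        feed.frequencies = pd.DataFrame(
            [{"trip_id": "t0", "start_time": "07:00:00", "end_time": "09:00:00", "headway_secs": 1800}]
        )
        out = expand_frequencies(feed)
        hw = stop_headways(out, {"WK"})
        assert hw["n_departures"].iloc[0] == 4  # 07:00 07:30 08:00 08:30
        assert np.isclose(hw["mean_headway_min"].iloc[0], 30.0)
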