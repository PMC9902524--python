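"""GTFS parsing and weekday daytime service-frequency analysis.

Transit access distinguishes three stop classes: any stop; stops with
average weekday daytime service every 30 min or better; and every 20 min
or better.  The service frequency at a stop is the mean of consecutive
gaps between its pooled departures — across all routes — inside the
daytime window (default 07:00-19:00) on a representative weekday (the
Mon-Fri day with the most scheduled departures; earliest day wins ties).
A stop needs at least two windowed departures for a defined headway;
otherwise both frequency classes are 0.

Times after 24:00:00 are valid GTFS (service-day semantics) and parse to
seconds past the service day's midnight.  ``frequencies.txt`` entries are
expanded to explicit departures before pooling.  ``calendar_dates.txt``
exceptions, when present, toggle a service on a given weekday if they
affect the majority of that weekday's dates in the feed span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import lonlat_to_xy

DAYTIME_WINDOW_S = (7 * 3600, 19 * 3600)
WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday")

_REQUIRED_FILES = ("stops.txt", "trips.txt", "stop_times.txt", "calendar.txt")


class GTFSFormatError(ValueError):
    """A required GTFS file is missing or structurally unreadable."""


@dataclass
class GTFSFeed:
    stops: pd.DataFrame
    trips: pd.DataFrame
    stop_times: pd.DataFrame
    calendar: pd.DataFrame
    calendar_dates: pd.DataFrame | None = None
    frequencies: pd.DataFrame | None = None
    n_bad_time_rows: int = 0


def parse_gtfs_time(value) -> float:
    """'HH:MM:SS' -> seconds past service-day midnight; hours may exceed 24."""
    parts = str(value).strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"unparseable GTFS time: {value!r}")
    h, m, s = (int(p) for p in parts)
    if m >= 60 or s >= 60 or h < 0 or m < 0 or s < 0:
        raise ValueError(f"unparseable GTFS time: {value!r}")
    return float(h * 3600 + m * 60 + s)


def parse_gtfs(directory, origin_lonlat: tuple[float, float] | None = None) -> GTFSFeed:
    """Load and type a GTFS directory.

    ``origin_lonlat`` anchors the projection of stop coordinates to the
    analysis plane; by default the feed's mean stop location is used.
    Rows with unparseable times are dropped and counted in
    ``n_bad_time_rows`` (reported via a warning).
    """
    directory = Path(directory)
    missing = [f for f in _REQUIRED_FILES if not (directory / f).exists()]
    if missing:
        raise GTFSFormatError(f"GTFS directory {directory} missing: {missing}")
    stops = pd.read_csv(directory / "stops.txt", dtype={"stop_id": str})
    trips = pd.read_csv(directory / "trips.txt", dtype={"trip_id": str, "service_id": str, "route_id": str})
    stop_times = pd.read_csv(directory / "stop_times.txt", dtype={"trip_id": str, "stop_id": str})
    calendar = pd.read_csv(directory / "calendar.txt", dtype={"service_id": str})

    n_bad = 0
    secs = []
    keep = []
    for t in stop_times["departure_time"]:
        try:
            secs.append(parse_gtfs_time(t))
            keep.append(True)
        except ValueError:
            secs.append(np.nan)
            keep.append(False)
            n_bad += 1
    stop_times = stop_times.assign(departure_s=secs)[np.asarray(keep)].reset_index(drop=True)
    if n_bad:
        warnings.warn(f"dropped {n_bad} stop_times row(s) with unparseable times")

    if origin_lonlat is None:
        origin_lonlat = (float(stops["stop_lon"].mean()), float(stops["stop_lat"].mean()))
    x, y = lonlat_to_xy(stops["stop_lon"], stops["stop_lat"], origin_lonlat[0], origin_lonlat[1])
    stops = stops.assign(x=x, y=y)
    if stops["stop_id"].duplicated().any():
        raise GTFSFormatError("duplicate stop_id in stops.txt")

    calendar_dates = None
    if (directory / "calendar_dates.txt").exists():
        calendar_dates = pd.read_csv(directory / "calendar_dates.txt", dtype={"service_id": str})
    frequencies = None
    if (directory / "frequencies.txt").exists():
        frequencies = pd.read_csv(directory / "frequencies.txt", dtype={"trip_id": str})

    feed = GTFSFeed(
        stops=stops,
        trips=trips,
        stop_times=stop_times,
        calendar=calendar,
        calendar_dates=calendar_dates,
        frequencies=frequencies,
        n_bad_time_rows=n_bad,
    )
    return expand_frequencies(feed)


def expand_frequencies(feed: GTFSFeed) -> GTFSFeed:
    """Rewrite frequency-based trips as explicit departures.

    Each headway block spawns copies of the template trip's stop_times at
    ``start_time, start_time + headway_secs, ...`` up to (excluding)
    ``end_time``, shifted by the offset of each stop from the template
    trip's first departure.
    """
    if feed.frequencies is None or feed.frequencies.empty:
        return feed
    st = feed.stop_times
    extra = []
    template_ids = set(feed.frequencies["trip_id"])
    base = st[st["trip_id"].isin(template_ids)]
    rest = st[~st["trip_id"].isin(template_ids)]
    for f in feed.frequencies.itertuples():
        tmpl = base[base["trip_id"] == f.trip_id].sort_values("departure_s")
        if tmpl.empty:
            continue
        t0 = float(tmpl["departure_s"].iloc[0])
        start = parse_gtfs_time(f.start_time)
        end = parse_gtfs_time(f.end_time)
        headway = float(f.headway_secs)
        k = 0
        while start + k * headway < end - 1e-9:
            dep0 = start + k * headway
            block = tmpl.copy()
            block["departure_s"] = dep0 + (block["departure_s"] - t0)
            block["trip_id"] = f"{f.trip_id}#freq{k}"
            extra.append(block)
            k += 1
    trips_extra = []
    trip_rows = feed.trips.set_index("trip_id")
    for block in extra:
        tid = block["trip_id"].iloc[0]
        src = tid.split("#freq")[0]
        row = trip_rows.loc[src].copy()
        row["trip_id"] = tid
        trips_extra.append(row)
    new_st = pd.concat([rest] + extra, ignore_index=True)
    new_trips = pd.concat(
        [feed.trips[~feed.trips["trip_id"].isin(template_ids)], pd.DataFrame(trips_extra)],
        ignore_index=True,
    )
    return GTFSFeed(
        stops=feed.stops,
        trips=new_trips,
        stop_times=new_st,
        calendar=feed.calendar,
        calendar_dates=feed.calendar_dates,
        frequencies=None,
        n_bad_time_rows=feed.n_bad_time_rows,
    )


def _weekday_service_ids(feed: GTFSFeed, day: str) -> set:
    cal = feed.calendar
    active = set(cal.loc[cal[day].astype(int) == 1, "service_id"])
    if feed.calendar_dates is not None and not feed.calendar_dates.empty:
        # an exception flips a service on this weekday only if it affects
        # the majority of that weekday's dates within the feed span
        day_index = WEEKDAYS.index(day) if day in WEEKDAYS else ["saturday", "sunday"].index(day) + 5
        cd = feed.calendar_dates.copy()
        cd["date"] = pd.to_datetime(cd["date"].astype(str), format="%Y%m%d")
        for svc, grp in cd.groupby("service_id"):
            rows = cal.loc[cal["service_id"] == svc]
            if rows.empty:
                continue
            start = pd.to_datetime(str(rows["start_date"].iloc[0]), format="%Y%m%d")
            end = pd.to_datetime(str(rows["end_date"].iloc[0]), format="%Y%m%d")
            dates = pd.date_range(start, end, freq="D")
            day_dates = dates[dates.dayofweek == day_index]
            if len(day_dates) == 0:
                continue
            hits = grp[grp["date"].isin(day_dates)]
            added = (hits["exception_type"].astype(int) == 1).sum()
            removed = (hits["exception_type"].astype(int) == 2).sum()
            if removed > len(day_dates) / 2:
                active.discard(svc)
            elif added > len(day_dates) / 2:
                active.add(svc)
    return active


def representative_weekday(feed: GTFSFeed) -> tuple[str | None, frozenset]:
    """The Mon-Fri day with the most scheduled departures, and its services.

    Ties break to the earliest day of the week.  A feed with no weekday
    service returns ``(None, frozenset())`` with a warning.
    """
    best_day, best_count, best_services = None, -1, frozenset()
    for day in WEEKDAYS:
        services = _weekday_service_ids(feed, day)
        if not services:
            continue
        trips = feed.trips.loc[feed.trips["service_id"].isin(services), "trip_id"]
        count = int(feed.stop_times["trip_id"].isin(set(trips)).sum())
        if count > best_count:
            best_day, best_count, best_services = day, count, frozenset(services)
    if best_day is None:
        warnings.warn("no weekday service in feed")
        return None, frozenset()
    return best_day, best_services


def stop_headways(
    feed: GTFSFeed,
    service_ids,
    window: tuple[float, float] = DAYTIME_WINDOW_S,
) -> pd.DataFrame:
    """Mean daytime headway and frequency classes per stop.

    Departures of trips running the selected services are pooled per stop
    within the window (inclusive at both ends), deduplicated by clock time
    (so duplicated schedules under another route do not halve the
    headway), and the mean of consecutive gaps is the stop's headway.
    Columns: stop_id, n_departures, mean_headway_min, class_30, class_20.
    """
    w0, w1 = window
    trip_ids = set(feed.trips.loc[feed.trips["service_id"].isin(set(service_ids)), "trip_id"])
    st = feed.stop_times
    windowed = st[
        st["trip_id"].isin(trip_ids) & (st["departure_s"] >= w0) & (st["departure_s"] <= w1)
    ]
    rows = []
    grouped = {k: g for k, g in windowed.groupby("stop_id")}
    for stop_id in feed.stops["stop_id"]:
        g = grouped.get(stop_id)
        if g is None:
            rows.append((stop_id, 0, np.nan, 0, 0))
            continue
        deps = np.unique(g["departure_s"].to_numpy(dtype=float))
        n = len(deps)
        if n < 2:
            rows.append((stop_id, n, np.nan, 0, 0))
            continue
        mean_headway = float(np.diff(deps).mean() / 60.0)
        rows.append((stop_id, n, mean_headway, int(mean_headway <= 30), int(mean_headway <= 20)))
    return pd.DataFrame(
        rows, columns=["stop_id", "n_departures", "mean_headway_min", "class_30", "class_20"]
    )


def transit_stop_layers(feed: GTFSFeed, headways: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The three transit destination layers: any / <=30 min / <=20 min stops."""
    stops = feed.stops.merge(headways, on="stop_id")
    base = stops[["stop_id", "x", "y"]]
    return {
        "pt_stop_any": base.reset_index(drop=True),
        "pt_stop_30min": base[stops["class_30"] == 1].reset_index(drop=True),
        "pt_stop_20min": base[stops["class_20"] == 1].reset_index(drop=True),
    }
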