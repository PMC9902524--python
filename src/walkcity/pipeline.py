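"""End-to-end orchestration: layers in, indicators and summaries out.

``analyze_city`` runs the full single-city chain: clean network ->
30 m sample points over populated cells -> 1000 m catchment densities ->
500 m access per destination class (with GTFS-derived service classes
when a feed is supplied) -> daily living and within-city walkability ->
hexagon neighbourhood summary -> population-weighted city percentages.

``compare_cities`` pools the hexagon records of several runs, standardises
density and daily-living components against the pooled distribution, and
attaches the between-city walkability (zero = all-cities average) plus a
group summary table, mirroring how multi-city benchmarking tables are
assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import access as access_mod
from . import catchments as catch_mod
from . import composite, summarise, transit
from .network import StreetNetwork, generate_sample_points, largest_component
from .region_grid import RegionBoundary, build_hex_grid
from .synthetic_city import CitySpec, SyntheticCity, generate_city, generate_gtfs


@dataclass
class RunParams:
    """Tunable analysis parameters with their conventional defaults."""

    sample_interval_m: float = 30.0
    catchment_cutoff_m: float = 1000.0
    access_threshold_m: float = 500.0
    distance_cap_m: float = 3200.0
    entry_spacing_m: float = 20.0
    snap_tolerance_m: float = 500.0
    gtfs_window_s: tuple = (7 * 3600, 19 * 3600)


@dataclass
class CityRun:
    """All per-city outputs of one analysis."""

    name: str
    points: pd.DataFrame
    hexes: pd.DataFrame
    hex_summary: pd.DataFrame
    city: dict
    income_group: str | None = None


def destination_layers(
    net: StreetNetwork,
    destinations: dict,
    params: RunParams,
    gtfs_dir=None,
    gtfs_origin=(0.0, 0.0),
) -> dict:
    """Snap raw destination inputs into the seven access classes."""
    layers = {}
    for label in ("food_market", "convenience"):
        raw = destinations.get(label)
        if raw is not None and not raw.empty:
            layers[label] = access_mod.snap_to_network(net, raw, params.snap_tolerance_m)
        else:
            layers[label] = pd.DataFrame()
    if gtfs_dir is not None:
        feed = transit.parse_gtfs(gtfs_dir, origin_lonlat=gtfs_origin)
        _, services = transit.representative_weekday(feed)
        headways = transit.stop_headways(feed, services, window=params.gtfs_window_s)
        for label, layer in transit.transit_stop_layers(feed, headways).items():
            if layer.empty:
                layers[label] = pd.DataFrame()
            else:
                pts = layer.rename(columns={"stop_id": "dest_id"})
                layers[label] = access_mod.snap_to_network(net, pts, params.snap_tolerance_m)
    else:
        raw = destinations.get("pt_stop")
        if raw is not None and not raw.empty:
            layers["pt_stop_any"] = access_mod.snap_to_network(net, raw, params.snap_tolerance_m)
        else:
            layers["pt_stop_any"] = pd.DataFrame()
        layers["pt_stop_30min"] = None  # unmeasurable without a schedule
        layers["pt_stop_20min"] = None
    pos = destinations.get("pos")
    if pos is not None and not pos.empty:
        any_layer, large_layer = access_mod.pos_entry_points(
            pos, net, spacing=params.entry_spacing_m, snap_tolerance=params.snap_tolerance_m
        )
        layers["pos_any_entry"] = any_layer
        layers["pos_large_entry"] = large_layer
    else:
        layers["pos_any_entry"] = pd.DataFrame()
        layers["pos_large_entry"] = pd.DataFrame()
    return {k: v for k, v in layers.items() if v is not None}


def analyze_city(
    net: StreetNetwork,
    region: RegionBoundary,
    grid: pd.DataFrame,
    destinations: dict,
    gtfs_dir=None,
    params: RunParams | None = None,
    name: str = "city",
    income_group: str | None = None,
) -> CityRun:
    params = params or RunParams()
    net = largest_component(net)
    hexes = build_hex_grid(region)
    points = generate_sample_points(
        net,
        interval=params.sample_interval_m,
        grid=grid,
        hexes=hexes,
        populated_only=True,
    )
    catchments = catch_mod.compute_catchments(net, points, grid, cutoff=params.catchment_cutoff_m)
    layers = destination_layers(net, destinations, params, gtfs_dir=gtfs_dir)
    table = access_mod.access_table(
        net, points, layers, cap=params.distance_cap_m, threshold=params.access_threshold_m
    )
    wide = access_mod.access_wide(table)
    indicators = composite.point_indicators(catchments, wide)
    indicators = indicators.merge(points[["point_id", "hex_id", "cell_id", "x", "y"]], on="point_id")
    indicators = composite.add_walkability(indicators, column="walkability_within")
    hex_summary = summarise.aggregate_to_hex(indicators, hexes, grid)
    city = summarise.city_percentages(hex_summary, name=name, income_group=income_group)
    return CityRun(
        name=name,
        points=indicators,
        hexes=hexes,
        hex_summary=hex_summary,
        city=city,
        income_group=income_group,
    )


def run_synthetic(spec: CitySpec, out_dir=None, name: str = "synthetic") -> CityRun:
    """Generate a synthetic city and run the full indicator chain on it."""
    city = generate_city(spec, name=name)
    gtfs_dir = None
    if spec.n_stops > 0:
        import tempfile

        gtfs_root = Path(out_dir) if out_dir is not None else Path(tempfile.mkdtemp())
        gtfs_dir = generate_gtfs(spec, city.destinations["pt_stop"], gtfs_root / "gtfs")
    run = analyze_city(
        city.net, city.region, city.grid, city.destinations, gtfs_dir=gtfs_dir, name=name
    )
    if out_dir is not None:
        summarise.export_outputs(
            out_dir,
            points=run.points,
            hex_summary=run.hex_summary,
            hexes=run.hexes,
            city=run.city,
            manifest={"spec": asdict(spec), "name": name},
        )
    return run


def compare_cities(runs: list[CityRun]) -> dict:
    """Between-city standardisation and group summary over several runs.

    Pools every city's hexagon records, z-scores population density,
    intersection density and daily living against the pooled distribution
    (population-size denominator), and sums them into
    ``walkability_between`` per hexagon.  Returns the pooled hex table and
    the per-city + group summary tables.
    """
    if len(runs) < 2:
        raise ValueError("between-city comparison needs at least 2 cities")
    pooled = pd.concat(
        [r.hex_summary.assign(city=r.name) for r in runs], ignore_index=True
    )
    comps = ["pop_density", "int_density", "daily_living"]
    z = {c: composite.standardise(pooled[c]) for c in comps}
    pooled["walkability_between"] = composite.walkability(z["pop_density"], z["int_density"], z["daily_living"])
    cities = pd.DataFrame([dict(r.city, income_group=r.income_group or "unknown") for r in runs])
    groups = summarise.group_summary(cities, grouping="income_group")
    return {"pooled_hexes": pooled, "cities": cities, "groups": groups}
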