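"""Deterministic synthetic study regions for end-to-end testing.

A synthetic city is a square region with a connected planar street
network (a block lattice, optionally perturbed into an "organic" variant),
a 250 m population grid with radially decaying density, clustered amenity
points snapped near the network, rectangular public-open-space polygons,
and a minimal weekday fixed-headway GTFS feed.  Everything derives from a
single integer seed through one named pseudo-random stream per layer, so
adding or regenerating one layer never perturbs the others and identical
specs reproduce byte-identical outputs.

Coordinates are planar metres in a local frame with the origin at the
region's south-west corner; the distance thresholds the indicators use are
all metric, so no geographic coordinates appear in fixtures (the GTFS
writer is the one exception — stop locations are exported through the
local equirectangular projection so feeds stay standards-conformant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .network import StreetNetwork, load_network
from .projection import xy_to_lonlat
from .region_grid import RegionBoundary, build_square_grid, set_population

_STREAMS = {
    "network": 11,
    "population": 23,
    "food_market": 31,
    "convenience": 37,
    "pt_stop": 41,
    "pos": 43,
}

GTFS_SERVICE_START_S = 6 * 3600
GTFS_SERVICE_END_S = 22 * 3600
GTFS_SPEED_M_S = 6.0


class InvalidSpecError(ValueError):
    """A CitySpec violates its invariants."""


class GenerationError(RuntimeError):
    """A layer cannot be generated under the requested spec."""


@dataclass(frozen=True)
class PosSpec:
    """One public-open-space polygon: target area and centroid placement."""

    area_ha: float
    placement: tuple[float, float] | str = "random"

    def __post_init__(self):
        if self.area_ha <= 0:
            raise InvalidSpecError("open-space area must be positive")


@dataclass(frozen=True)
class CitySpec:
    """Complete recipe for a synthetic study region."""

    seed: int = 0
    layout: str = "grid"  # or "organic"
    extent_m: float = 2000.0
    block_m: float = 250.0
    pop_total: int = 20_000
    pop_gradient: float = 0.5  # exponential decay rate per km of radius
    n_food: int = 8
    n_convenience: int = 8
    n_stops: int = 12
    pos_polygons: tuple[PosSpec, ...] = (
        PosSpec(0.8),
        PosSpec(1.2),
        PosSpec(2.5),
    )
    transit_headway_min: float = 20.0
    cluster_factor: float = 0.5
    edge_removal_frac: float = 0.15  # organic layout only

    def __post_init__(self):
        if self.layout not in ("grid", "organic"):
            raise InvalidSpecError(f"unknown layout {self.layout!r}")
        if self.extent_m < 4 * self.block_m:
            raise InvalidSpecError("extent must cover at least 4x4 blocks worth of span")
        if min(self.pop_total, self.n_food, self.n_convenience, self.n_stops) < 0:
            raise InvalidSpecError("counts must be nonnegative")
        if not (0.0 <= self.cluster_factor <= 1.0):
            raise InvalidSpecError("cluster_factor must lie in [0, 1]")
        if self.transit_headway_min <= 0:
            raise InvalidSpecError("transit headway must be positive")

    def rng(self, layer: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[layer]])


def region_for(spec: CitySpec, name: str = "synthetic") -> RegionBoundary:
    return RegionBoundary(box(0.0, 0.0, spec.extent_m, spec.extent_m), name=name)


def generate_street_network(spec: CitySpec) -> StreetNetwork:
    """Square block lattice; ``organic`` jitters nodes and prunes edges.

    The organic variant perturbs every interior node by seeded noise of
    magnitude at most ``0.3 * block_m`` and removes a seeded fraction of
    edges, skipping any removal that would disconnect the network.
    """
    n_side = int(round(spec.extent_m / spec.block_m)) + 1
    if n_side < 3:
        raise InvalidSpecError("extent/block combination yields fewer than 2x2 blocks")
    rng = spec.rng("network")
    ids = np.arange(n_side * n_side).reshape(n_side, n_side)
    xs, ys = np.meshgrid(
        np.arange(n_side) * spec.block_m, np.arange(n_side) * spec.block_m, indexing="xy"
    )
    xs = xs.astype(float)
    ys = ys.astype(float)
    if spec.layout == "organic":
        r = 0.3 * spec.block_m * np.sqrt(rng.random(ids.shape))
        theta = 2 * np.pi * rng.random(ids.shape)
        interior = np.zeros(ids.shape, dtype=bool)
        interior[1:-1, 1:-1] = True
        xs = xs + np.where(interior, r * np.cos(theta), 0.0)
        ys = ys + np.where(interior, r * np.sin(theta), 0.0)
    nodes = pd.DataFrame(
        {"node_id": ids.ravel(), "x": xs.ravel(), "y": ys.ravel()}
    )
    pairs = []
    for r_ in range(n_side):
        for c in range(n_side):
            if c + 1 < n_side:
                pairs.append((ids[r_, c], ids[r_, c + 1]))
            if r_ + 1 < n_side:
                pairs.append((ids[r_, c], ids[r_ + 1, c]))
    if spec.layout == "organic" and spec.edge_removal_frac > 0:
        g = nx.Graph(pairs)
        target = int(round(spec.edge_removal_frac * len(pairs)))
        order = rng.permutation(len(pairs))
        removed = 0
        keep = np.ones(len(pairs), dtype=bool)
        for i in order:
            if removed >= target:
                break
            u, v = pairs[i]
            g.remove_edge(u, v)
            if nx.is_connected(g):
                keep[i] = False
                removed += 1
            else:
                g.add_edge(u, v)
        pairs = [p for p, k in zip(pairs, keep) if k]
    xy = dict(zip(nodes["node_id"], zip(nodes["x"], nodes["y"])))
    edges = pd.DataFrame(
        {
            "edge_id": np.arange(len(pairs)),
            "u": [p[0] for p in pairs],
            "v": [p[1] for p in pairs],
            "geometry": [LineString([xy[u], xy[v]]) for u, v in pairs],
        }
    )
    return load_network(nodes, edges)


def generate_population_grid(spec: CitySpec, region: RegionBoundary) -> pd.DataFrame:
    """250 m grid with a seeded multinomial draw of ``pop_total`` persons.

    Expected cell weights decay exponentially with distance from the
    region centre at ``pop_gradient`` per km; a zero gradient gives
    uniform expected weights.  Cell counts always sum exactly to the
    total.
    """
    grid = build_square_grid(region)
    cx = (region.bounds[0] + region.bounds[2]) / 2.0
    cy = (region.bounds[1] + region.bounds[3]) / 2.0
    centroids = np.array([(g.centroid.x, g.centroid.y) for g in grid["geometry"]])
    r_km = np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy) / 1000.0
    weights = np.exp(-spec.pop_gradient * r_km)
    weights = weights / weights.sum()
    rng = spec.rng("population")
    counts = rng.multinomial(int(spec.pop_total), weights)
    return set_population(grid, counts.astype(float))


def _network_cum_lengths(net: StreetNetwork):
    lengths = net.edges["length_m"].to_numpy(dtype=float)
    return lengths, np.cumsum(lengths)


def _sample_on_network(net: StreetNetwork, rng, n: int) -> np.ndarray:
    """n positions uniform over network length -> array of (edge_row, offset)."""
    lengths, cum = _network_cum_lengths(net)
    u = rng.random(n) * cum[-1]
    rows = np.searchsorted(cum, u, side="right")
    offs = u - np.concatenate([[0.0], cum[:-1]])[rows]
    return np.column_stack([rows, offs])


def _edge_point(net: StreetNetwork, row: int, off: float):
    e = net.edges.iloc[int(row)]
    pt = e.geometry.interpolate(min(off, e.length_m) / e.length_m, normalized=True)
    return e, pt


def generate_destinations(spec: CitySpec, net: StreetNetwork) -> dict[str, pd.DataFrame]:
    """Amenity point layers and open-space polygons.

    Points are placed on the network with a small perpendicular jitter
    (<= 15 m, so every destination snaps back within 20 m).  With
    ``cluster_factor`` c each point is, with probability c, drawn close to
    one of a few seeded cluster centres instead of uniformly over the
    network, emulating shopping strips.  Open-space polygons are
    axis-aligned rectangles of exactly the requested areas.

    Returns ``{"food_market": ..., "convenience": ..., "pt_stop": ...}``
    point tables (dest_id, x, y) plus ``"pos"`` with polygon geometries.
    """
    if len(net.edges) == 0:
        raise GenerationError("cannot place destinations on an empty network")
    out: dict[str, pd.DataFrame] = {}
    capacity = int(net.total_length_m // 10.0)
    for label, count in (
        ("food_market", spec.n_food),
        ("convenience", spec.n_convenience),
        ("pt_stop", spec.n_stops),
    ):
        if count > capacity:
            raise GenerationError(
                f"{label}: requested {count} exceeds ~{capacity} placement sites"
            )
        rng = spec.rng(label)
        n_clusters = max(1, math.ceil(count / 5))
        centres = _sample_on_network(net, rng, n_clusters)
        rows = []
        for i in range(count):
            if rng.random() < spec.cluster_factor:
                crow, coff = centres[rng.integers(n_clusters)]
                e = net.edges.iloc[int(crow)]
                off = float(np.clip(coff + rng.normal(0.0, spec.block_m / 8.0), 0.0, e.length_m))
                erow = int(crow)
            else:
                erow, off = _sample_on_network(net, rng, 1)[0]
                erow = int(erow)
            e, pt = _edge_point(net, erow, off)
            (x0, y0), (x1, y1) = e.geometry.coords[0], e.geometry.coords[-1]
            L = math.hypot(x1 - x0, y1 - y0) or 1.0
            nx_, ny_ = -(y1 - y0) / L, (x1 - x0) / L  # unit normal
            jitter = rng.uniform(-15.0, 15.0)
            rows.append((i, pt.x + jitter * nx_, pt.y + jitter * ny_))
        out[label] = pd.DataFrame(rows, columns=["dest_id", "x", "y"])

    rng = spec.rng("pos")
    pos_rows = []
    for i, ps in enumerate(spec.pos_polygons):
        area_m2 = ps.area_ha * 10_000.0
        aspect = rng.uniform(0.6, 1.6)
        w = math.sqrt(area_m2 * aspect)
        h = area_m2 / w
        if ps.placement == "random":
            cx = rng.uniform(w / 2, max(w / 2, spec.extent_m - w / 2))
            cy = rng.uniform(h / 2, max(h / 2, spec.extent_m - h / 2))
        else:
            cx, cy = ps.placement
        poly = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        pos_rows.append({"pos_id": i, "area_ha": ps.area_ha, "geometry": poly})
    out["pos"] = pd.DataFrame(pos_rows)
    return out


def _format_gtfs_time(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def generate_gtfs(spec: CitySpec, stops: pd.DataFrame, out_dir) -> Path:
    """Write a minimal weekday fixed-headway GTFS feed for the stop layer.

    One route serves every stop in a nearest-neighbour ordering; trips
    depart the first stop every ``transit_headway_min`` minutes from 06:00
    through 22:00 inclusive (so a 20 min headway yields 49 departures per
    stop per weekday).  The calendar runs Monday-Friday only.  Stop
    coordinates go through the local projection anchored at (0, 0).
    """
    if stops.empty:
        raise GenerationError("GTFS generation needs at least one stop")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    xy = stops[["x", "y"]].to_numpy(dtype=float)
    order = [0]
    remaining = set(range(1, len(xy)))
    while remaining:  # greedy nearest-neighbour stop sequence
        last = xy[order[-1]]
        nxt = min(remaining, key=lambda j: (np.hypot(*(xy[j] - last)), j))
        order.append(nxt)
        remaining.discard(nxt)

    lon, lat = xy_to_lonlat(xy[:, 0], xy[:, 1])
    stop_ids = [f"S{int(i):04d}" for i in stops["dest_id"]]
    stops_txt = pd.DataFrame(
        {
            "stop_id": stop_ids,
            "stop_name": [f"Stop {i}" for i in stops["dest_id"]],
            "stop_lat": np.round(lat, 7),
            "stop_lon": np.round(lon, 7),
        }
    )

    offsets = [0.0]
    for a, b in zip(order[:-1], order[1:]):
        offsets.append(offsets[-1] + float(np.hypot(*(xy[b] - xy[a]))) / GTFS_SPEED_M_S)

    headway_s = spec.transit_headway_min * 60.0
    n_trips = int(math.floor((GTFS_SERVICE_END_S - GTFS_SERVICE_START_S) / headway_s)) + 1
    trips_rows, st_rows = [], []
    for k in range(n_trips):
        trip_id = f"T{k:04d}"
        trips_rows.append({"route_id": "R1", "service_id": "WK", "trip_id": trip_id})
        t0 = GTFS_SERVICE_START_S + k * headway_s
        for seq, j in enumerate(order):
            t = _format_gtfs_time(t0 + offsets[seq])
            st_rows.append(
                {
                    "trip_id": trip_id,
                    "arrival_time": t,
                    "departure_time": t,
                    "stop_id": stop_ids[j],
                    "stop_sequence": seq + 1,
                }
            )

    pd.DataFrame(
        [{"agency_id": "SYN", "agency_name": "Synthetic Transit", "agency_url": "https://example.org", "agency_timezone": "Etc/UTC"}]
    ).to_csv(out_dir / "agency.txt", index=False)
    stops_txt.to_csv(out_dir / "stops.txt", index=False)
    pd.DataFrame(
        [{"route_id": "R1", "agency_id": "SYN", "route_short_name": "1", "route_long_name": "Loop", "route_type": 3}]
    ).to_csv(out_dir / "routes.txt", index=False)
    pd.DataFrame(trips_rows).to_csv(out_dir / "trips.txt", index=False)
    pd.DataFrame(st_rows).to_csv(out_dir / "stop_times.txt", index=False)
    pd.DataFrame(
        [
            {
                "service_id": "WK",
                "monday": 1,
                "tuesday": 1,
                "wednesday": 1,
                "thursday": 1,
                "friday": 1,
                "saturday": 0,
                "sunday": 0,
                "start_date": 20150105,
                "end_date": 20151231,
            }
        ]
    ).to_csv(out_dir / "calendar.txt", index=False)
    return out_dir


@dataclass
class SyntheticCity:
    """In-memory bundle of all generated layers for one spec."""

    spec: CitySpec
    region: RegionBoundary
    net: StreetNetwork
    grid: pd.DataFrame
    destinations: dict[str, pd.DataFrame]


def generate_city(spec: CitySpec, name: str = "synthetic") -> SyntheticCity:
    region = region_for(spec, name)
    net = generate_street_network(spec)
    grid = generate_population_grid(spec, region)
    destinations = generate_destinations(spec, net)
    return SyntheticCity(spec=spec, region=region, net=net, grid=grid, destinations=destinations)


def write_city(city: SyntheticCity, out_dir) -> dict:
    """Write every layer (GeoJSON + GTFS + manifest) to a directory."""
    from dataclasses import asdict

    from .geojson_io import write_geojson
    from .network import write_network

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_network(city.net, out_dir / "nodes.geojson", out_dir / "edges.geojson")
    write_geojson(city.grid, out_dir / "population_grid.geojson")
    region_df = pd.DataFrame(
        [{"name": city.region.name, "crs_id": city.region.crs_id, "geometry": city.region.polygon}]
    )
    write_geojson(region_df, out_dir / "region.geojson")
    for label in ("food_market", "convenience", "pt_stop"):
        layer = city.destinations[label].copy()
        layer["geometry"] = [Point(x, y) for x, y in zip(layer["x"], layer["y"])]
        write_geojson(layer, out_dir / f"dest_{label}.geojson")
    write_geojson(city.destinations["pos"], out_dir / "open_space.geojson")
    gtfs_dir = None
    if city.spec.n_stops > 0:
        gtfs_dir = generate_gtfs(city.spec, city.destinations["pt_stop"], out_dir / "gtfs")
    manifest = asdict(city.spec)
    manifest["pos_polygons"] = [
        {"area_ha": p.area_ha, "placement": list(p.placement) if not isinstance(p.placement, str) else p.placement}
        for p in city.spec.pos_polygons
    ]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"dir": out_dir, "gtfs": gtfs_dir}


@dataclass
class PlantedCity:
    """A grid city with an exactly known access fraction for food markets."""

    net: StreetNetwork
    region: RegionBoundary
    grid: pd.DataFrame
    food_market: pd.DataFrame  # may be empty when p = 0
    true_fraction: float


def generate_planted_access_city(
    p: float,
    extent_m: float = 4000.0,
    block_m: float = 250.0,
    pop_total: float = 10_000.0,
) -> PlantedCity:
    """Construct a city whose population-weighted food access fraction is ``p``.

    Markets saturate every street node in a western zone; a 750 m
    unpopulated buffer band separates it from the eastern zone so no
    populated sample point sits within 500 m of the far side's regime.
    Western cells carry ``p * pop_total`` persons spread uniformly and
    eastern cells the remainder, making the planted population-weighted
    access fraction exactly ``p`` independent of the spatial engine under
    test.
    """
    if not (0.0 <= p <= 1.0):
        raise InvalidSpecError("p must lie in [0, 1]")
    spec = CitySpec(seed=0, layout="grid", extent_m=extent_m, block_m=block_m)
    net = generate_street_network(spec)
    region = region_for(spec, name=f"planted-p{p:g}")
    grid = build_square_grid(region)
    n_side = int(round(extent_m / block_m))
    m = n_side // 2  # markets fill node columns < m

    col = grid["col"].to_numpy()
    pops = np.zeros(len(grid), dtype=float)
    if p <= 0.0:
        pops[:] = pop_total / len(grid)
        markets = pd.DataFrame(columns=["dest_id", "x", "y"])
    elif p >= 1.0:
        pops[:] = pop_total / len(grid)
        node_mask = net.nodes["node_id"] >= 0
        markets = pd.DataFrame(
            {
                "dest_id": np.arange(node_mask.sum()),
                "x": net.nodes.loc[node_mask, "x"].to_numpy(),
                "y": net.nodes.loc[node_mask, "y"].to_numpy(),
            }
        )
    else:
        west = col <= m - 2
        dead = (col >= m - 1) & (col <= m + 1)
        east = col >= m + 2
        pops[west] = p * pop_total / west.sum()
        pops[east] = (1.0 - p) * pop_total / east.sum()
        pops[dead] = 0.0
        nodes = net.nodes
        mask = nodes["x"] < m * block_m - 1.0
        markets = pd.DataFrame(
            {
                "dest_id": np.arange(int(mask.sum())),
                "x": nodes.loc[mask, "x"].to_numpy(),
                "y": nodes.loc[mask, "y"].to_numpy(),
            }
        )
    grid = set_population(grid, pops)
    return PlantedCity(net=net, region=region, grid=grid, food_market=markets, true_fraction=float(p))
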