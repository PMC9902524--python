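"""Walkable catchments: the 1000 m reachable network and its grid footprint.

Each sample point's local neighbourhood is the part of the pedestrian
network reachable within a distance cutoff (default 1000 m, roughly a
13-minute walk).  Instead of buffering the reached segments into a polygon
("sausage buffer"), the catchment is approximated by the set of 250 m grid
cells the reached network intersects — a computationally tractable stand-in
whose area is ``n_cells * 0.0625 km^2``.

Population in the catchment is the whole-cell sum over member cells (no
areal interpolation; this overstates the true buffer population slightly
and is documented as a bias source).  Street intersections are nodes of
degree >= 3 whose network distance from the origin is within the cutoff;
the far endpoint of a partially reached edge does not count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.ops import substring
from shapely.strtree import STRtree

from .network import StreetNetwork, shortest_distances
from .region_grid import CELL_AREA_KM2

CATCHMENT_CUTOFF_M = 1000.0


class UndefinedDensityError(ValueError):
    """A catchment with no grid cells has no defined density."""


def _merge_intervals(ivs):
    ivs = sorted((a, b) for a, b in ivs if b - a > 1e-9)
    merged = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def reachable_network(
    net: StreetNetwork,
    edge_id: int,
    offset_m: float,
    cutoff: float = CATCHMENT_CUTOFF_M,
    node_distances: dict | None = None,
) -> pd.DataFrame:
    """Edge sub-segments within network distance ``cutoff`` of the origin.

    Returns a DataFrame ``(edge_id, start_m, end_m)`` of merged intervals
    measured along each edge from its lower-id endpoint.  Partial edges are
    trimmed exactly at the cutoff; portions reached from both endpoints
    (around loops) are merged without double counting.
    """
    dist = (
        node_distances
        if node_distances is not None
        else shortest_distances(net, edge_id, offset_m, cutoff)
    )
    rows = []
    for e in net.edges.itertuples():
        L = float(e.length_m)
        ivs = []
        if e.edge_id == edge_id:
            ivs.append((max(0.0, offset_m - cutoff), min(L, offset_m + cutoff)))
        du = dist.get(int(e.u))
        dv = dist.get(int(e.v))
        if du is not None and du <= cutoff:
            ivs.append((0.0, min(L, cutoff - du)))
        if dv is not None and dv <= cutoff:
            ivs.append((max(0.0, L - (cutoff - dv)), L))
        for a, b in _merge_intervals(ivs):
            rows.append((int(e.edge_id), a, b))
    return pd.DataFrame(rows, columns=["edge_id", "start_m", "end_m"])


def reached_geometries(net: StreetNetwork, reached: pd.DataFrame):
    """Shapely sub-segment geometries for a reached-edge table."""
    geoms = []
    by_id = net.edge_by_id
    for r in reached.itertuples():
        geom = by_id.loc[r.edge_id, "geometry"]
        geoms.append(substring(geom, r.start_m, r.end_m))
    return geoms


def reached_length(reached: pd.DataFrame) -> float:
    return float((reached["end_m"] - reached["start_m"]).sum())


def catchment_cells(net: StreetNetwork, reached: pd.DataFrame, grid: pd.DataFrame) -> set:
    """Grid cells whose square is intersected by any reached sub-segment."""
    if reached.empty:
        warnings.warn("empty reached network: catchment has no cells")
        return set()
    geoms = reached_geometries(net, reached)
    tree = STRtree(list(grid["geometry"]))
    cell_ids = grid["cell_id"].to_numpy()
    _, cell_idx = tree.query(geoms, predicate="intersects")
    return set(int(c) for c in cell_ids[np.unique(cell_idx)])


def catchment_summary(
    cells: set,
    reached: pd.DataFrame,
    grid: pd.DataFrame,
    net: StreetNetwork,
    node_distances: dict,
    cutoff: float = CATCHMENT_CUTOFF_M,
) -> dict:
    """Population and street-intersection densities of one catchment.

    Densities divide whole-cell population and the count of reached
    degree->=3 nodes by the cell-union area ``len(cells) * 0.0625 km^2``.
    """
    if not cells:
        raise UndefinedDensityError("catchment has no cells; densities undefined")
    area_km2 = len(cells) * CELL_AREA_KM2
    pop = float(grid.loc[grid["cell_id"].isin(cells), "population"].sum())
    deg = net.degrees
    n_int = sum(
        1 for n, d in node_distances.items() if d <= cutoff and deg.get(n, 0) >= 3
    )
    return {
        "n_cells": len(cells),
        "area_km2": area_km2,
        "population": pop,
        "intersections": int(n_int),
        "pop_density": pop / area_km2,
        "int_density": n_int / area_km2,
    }


def compute_catchments(
    net: StreetNetwork,
    points: pd.DataFrame,
    grid: pd.DataFrame,
    cutoff: float = CATCHMENT_CUTOFF_M,
) -> pd.DataFrame:
    """Catchment summary table for every sample point.

    One origin at a time: a Dijkstra from the point's half-edges, interval
    trimming at the cutoff, cell intersection, then density arithmetic.
    """
    grid_tree = STRtree(list(grid["geometry"]))
    cell_ids = grid["cell_id"].to_numpy()
    rows = []
    for p in points.itertuples():
        dist = shortest_distances(net, p.edge_id, p.offset_m, cutoff)
        reached = reachable_network(net, p.edge_id, p.offset_m, cutoff, node_distances=dist)
        geoms = reached_geometries(net, reached)
        _, cidx = grid_tree.query(geoms, predicate="intersects")
        cells = set(int(c) for c in cell_ids[np.unique(cidx)])
        if not cells:
            warnings.warn(f"point {p.point_id}: no catchment cells")
            continue
        summary = catchment_summary(cells, reached, grid, net, dist, cutoff)
        summary["point_id"] = int(p.point_id)
        rows.append(summary)
    cols = ["point_id", "n_cells", "area_km2", "population", "intersections", "pop_density", "int_density"]
    return pd.DataFrame(rows, columns=cols)
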