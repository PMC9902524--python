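"""Destination access: snapping, open-space entries, nearest distances, 500 m score.

Destinations (healthy-food markets, convenience stores, transit stops,
public-open-space entry points) are snapped to the nearest point on the
pedestrian network.  For each sample point the network distance to the
nearest destination of each class is computed, censored at a search cap
(default 3200 m), and scored against the 500 m accessibility threshold:
``binary = 1`` iff the distance is within (<=) the threshold, 0 otherwise
— censored distances always score 0.

Open-space access uses entry points generated every 20 m along each
polygon's boundary; the "large" class keeps only entries of polygons
strictly larger than 1.5 ha.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .network import StreetNetwork

ACCESS_THRESHOLD_M = 500.0
DISTANCE_CAP_M = 3200.0
SNAP_TOLERANCE_M = 500.0
ENTRY_SPACING_M = 20.0
LARGE_POS_THRESHOLD_HA = 1.5

DESTINATION_CLASSES = (
    "food_market",
    "convenience",
    "pt_stop_any",
    "pt_stop_30min",
    "pt_stop_20min",
    "pos_any_entry",
    "pos_large_entry",
)


class EmptyLayerError(ValueError):
    """No destination in the layer could be snapped to the network."""


def snap_to_network(
    net: StreetNetwork, points: pd.DataFrame, tolerance: float = SNAP_TOLERANCE_M
) -> pd.DataFrame:
    """Snap raw destination points to their nearest edge location.

    ``points`` needs ``x``/``y`` columns (``dest_id`` added if absent).
    Returns the layer with ``edge_id``, ``offset_m`` (from the lower-id
    endpoint) and ``snap_dist_m``; ties between equidistant edges go to the
    lower edge id.  Points farther than ``tolerance`` from every edge are
    excluded with a warning; an entirely unsnappable layer is an error.
    """
    if len(net.edges) == 0:
        raise ValueError("empty network")
    pts = points.copy().reset_index(drop=True)
    if "dest_id" not in pts.columns:
        pts.insert(0, "dest_id", np.arange(len(pts)))
    geoms = shapely.points(pts["x"].to_numpy(dtype=float), pts["y"].to_numpy(dtype=float))
    edge_geoms = np.asarray(net.edges["geometry"], dtype=object)
    edge_ids = net.edges["edge_id"].to_numpy()
    lengths = net.edges["length_m"].to_numpy(dtype=float)
    snapped = []
    for i, g in enumerate(geoms):
        d = shapely.distance(edge_geoms, g)
        j = int(np.argmin(d))  # edges sorted by edge_id: first argmin = lowest id
        if d[j] > tolerance:
            snapped.append((np.nan, np.nan, float(d[j]), False))
            continue
        geom = edge_geoms[j]
        # offset along the polyline, rescaled to the recorded metric length
        frac = geom.project(g, normalized=True)
        snapped.append((int(edge_ids[j]), float(frac * lengths[j]), float(d[j]), True))
    res = pd.DataFrame(snapped, columns=["edge_id", "offset_m", "snap_dist_m", "snapped"])
    out = pd.concat([pts, res], axis=1)
    n_dropped = int((~out["snapped"]).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} destination(s) beyond {tolerance} m snap tolerance; excluded")
    out = out[out["snapped"]].drop(columns=["snapped"]).reset_index(drop=True)
    if out.empty:
        raise EmptyLayerError("no destination could be snapped to the network")
    out["edge_id"] = out["edge_id"].astype(int)
    return out


def pos_entry_points(
    pos: pd.DataFrame,
    net: StreetNetwork,
    spacing: float = ENTRY_SPACING_M,
    area_class_threshold_ha: float = LARGE_POS_THRESHOLD_HA,
    snap_tolerance: float = SNAP_TOLERANCE_M,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entry points along open-space boundaries, snapped to the network.

    Entries are generated every ``spacing`` metres along each polygon's
    exterior ring (starting at its first vertex).  Returns the
    ``pos_any_entry`` layer (all polygons) and the ``pos_large_entry``
    layer (only polygons strictly larger than the area-class threshold).
    """
    rows = []
    for r in pos.itertuples():
        poly = r.geometry
        area_ha = poly.area / 10_000.0
        if poly.is_empty or area_ha <= 0:
            warnings.warn(f"open-space polygon {r.Index} degenerate; skipped")
            continue
        ring = poly.exterior
        n = max(1, int(np.floor(ring.length / spacing)))
        for k in range(n):
            pt = ring.interpolate(k * spacing)
            rows.append((int(r.Index), area_ha, pt.x, pt.y))
    raw = pd.DataFrame(rows, columns=["pos_index", "area_ha", "x", "y"])
    if raw.empty:
        raise EmptyLayerError("no valid open-space polygons")
    any_layer = snap_to_network(net, raw, tolerance=snap_tolerance)
    large = raw[raw["area_ha"] > area_class_threshold_ha].reset_index(drop=True)
    if large.empty:
        large_layer = large.assign(edge_id=pd.Series(dtype=int), offset_m=pd.Series(dtype=float))
    else:
        large_layer = snap_to_network(net, large, tolerance=snap_tolerance)
    return any_layer, large_layer


def _destination_distance_map(net: StreetNetwork, layer: pd.DataFrame, cap: float):
    """Multi-source Dijkstra: distance from every node to the nearest destination.

    Destinations sit mid-edge, so edges carrying destinations are split
    into chains through pseudo-nodes in a routing copy of the graph.
    Returns (node -> distance map, {edge_id: [offsets]} for same-edge hits).
    """
    g = net.graph.copy()
    by_edge: dict[int, list[float]] = {}
    sources = []
    for r in layer.itertuples():
        by_edge.setdefault(int(r.edge_id), []).append(float(r.offset_m))
    for eid, offs in by_edge.items():
        e = net.edge_record(eid)
        u, v, L = int(e.u), int(e.v), float(e.length_m)
        if not g.has_edge(u, v):
            continue  # parallel duplicate not in routing graph
        g.remove_edge(u, v)
        chain = [(u, 0.0)]
        for k, off in enumerate(sorted(set(offs))):
            node = ("dest", eid, k)
            sources.append(node)
            chain.append((node, off))
        chain.append((v, L))
        for (a, pa), (b, pb) in zip(chain[:-1], chain[1:]):
            w = max(pb - pa, 0.0)
            if g.has_edge(a, b):
                w = min(w, g[a][b]["length_m"])
            g.add_edge(a, b, length_m=w)
    if not sources:
        return {}, by_edge
    dmap = nx.multi_source_dijkstra_path_length(g, sources, cutoff=cap, weight="length_m")
    node_map = {n: d for n, d in dmap.items() if not isinstance(n, tuple)}
    return node_map, by_edge


def nearest_distances(
    net: StreetNetwork,
    points: pd.DataFrame,
    layer: pd.DataFrame,
    cap: float = DISTANCE_CAP_M,
) -> pd.DataFrame:
    """Nearest network distance from each sample point to a destination layer.

    Returns ``(point_id, distance_m, censored)``: distances beyond ``cap``
    (or with no destination at all) are censored at the cap.  An empty
    layer yields an all-censored result with a warning rather than an
    error, mirroring cities where a destination class is absent.
    """
    if layer is None or layer.empty:
        warnings.warn("empty destination layer: all distances censored")
        return pd.DataFrame(
            {
                "point_id": points["point_id"].to_numpy(),
                "distance_m": cap,
                "censored": True,
            }
        )
    node_map, by_edge = _destination_distance_map(net, layer, cap)
    edge_info = net.edge_by_id
    out = []
    for p in points.itertuples():
        e = edge_info.loc[p.edge_id]
        u, v, L = int(e.u), int(e.v), float(e.length_m)
        o = float(p.offset_m)
        best = np.inf
        du = node_map.get(u)
        dv = node_map.get(v)
        if du is not None:
            best = min(best, o + du)
        if dv is not None:
            best = min(best, (L - o) + dv)
        for off in by_edge.get(int(p.edge_id), ()):
            best = min(best, abs(o - off))
        censored = not (best <= cap)
        out.append((int(p.point_id), cap if censored else float(best), censored))
    return pd.DataFrame(out, columns=["point_id", "distance_m", "censored"])


def binary_access(distance_m, censored=None, threshold: float = ACCESS_THRESHOLD_M):
    """500 m binary access score: 1 iff the distance is within the threshold.

    "Within" is inclusive: exactly 500.0 m scores 1.  Censored distances
    score 0.  Accepts scalars or vectors.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative access distance")
    score = (d <= threshold).astype(int)
    if censored is not None:
        score = np.where(np.asarray(censored, dtype=bool), 0, score)
    if np.isscalar(distance_m) or d.ndim == 0:
        return int(score)
    return score


def access_table(
    net: StreetNetwork,
    points: pd.DataFrame,
    layers: dict[str, pd.DataFrame],
    cap: float = DISTANCE_CAP_M,
    threshold: float = ACCESS_THRESHOLD_M,
) -> pd.DataFrame:
    """Long-format access table over all destination classes.

    Columns: point_id, class_label, distance_m, censored, binary.
    """
    frames = []
    for label, layer in layers.items():
        res = nearest_distances(net, points, layer, cap=cap)
        res.insert(1, "class_label", label)
        res["binary"] = binary_access(res["distance_m"], res["censored"], threshold)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def access_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long access table to one binary column per class."""
    wide = table.pivot(index="point_id", columns="class_label", values="binary")
    wide.columns = [f"access_{c}" for c in wide.columns]
    return wide.reset_index()
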