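"""Pedestrian street network model, sample points and shortest-path services.

The walking network is undirected: every edge can be traversed both ways
regardless of any one-way attribute in the source data.  Edges are stored
with ``u <= v`` and their geometry oriented from ``u`` to ``v``, so offsets
along an edge are always measured from the endpoint with the lower node id
and outputs do not depend on the direction edges were digitised in.

Sample points — the residential proxy locations all indicators are
evaluated at — are laid every ``interval`` metres (default 30 m) along each
edge: at offsets ``interval, 2*interval, ..., k*interval`` with
``k = floor((L - eps) / interval)`` and ``eps = 1 mm`` so an edge whose
length is an exact multiple of the interval does not place a point on its
end node.  Edges shorter than the interval carry a single midpoint sample.
Points falling in grid cells with zero population can be dropped so that
indicators are only evaluated where people live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

SAMPLE_INTERVAL_M = 30.0
_EPS_M = 1e-3  # 1 mm guard in the sample-offset floor rule


class NetworkIntegrityError(ValueError):
    """Edge tables reference missing nodes or carry duplicate/invalid rows."""


@dataclass
class StreetNetwork:
    """Undirected street network as node and edge tables.

    ``nodes``: node_id, x, y.  ``edges``: edge_id, u, v, length_m, geometry
    (LineString from u to v, ``u <= v``).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes["node_id"].tolist())
        for e in self.edges.itertuples():
            # parallel edges: keep the shortest (walking distance semantics)
            if g.has_edge(e.u, e.v):
                if g[e.u][e.v]["length_m"] <= e.length_m:
                    continue
            g.add_edge(e.u, e.v, length_m=e.length_m, edge_id=e.edge_id)
        return g

    @cached_property
    def degrees(self) -> pd.Series:
        deg = self.graph.degree()
        return pd.Series({n: d for n, d in deg}, name="degree")

    @cached_property
    def node_xy(self) -> dict:
        return {
            int(n): (float(x), float(y))
            for n, x, y in zip(self.nodes["node_id"], self.nodes["x"], self.nodes["y"])
        }

    @cached_property
    def edge_by_id(self) -> pd.DataFrame:
        return self.edges.set_index("edge_id")

    @cached_property
    def edge_tree(self) -> STRtree:
        return STRtree(list(self.edges["geometry"]))

    @property
    def total_length_m(self) -> float:
        return float(self.edges["length_m"].sum())

    def edge_record(self, edge_id: int):
        return self.edge_by_id.loc[edge_id]


def load_network(nodes: pd.DataFrame, edges: pd.DataFrame) -> StreetNetwork:
    """Validate node/edge tables and build a :class:`StreetNetwork`.

    Missing ``length_m`` values are derived from edge geometry; edges with
    no geometry get a straight-line geometry between their endpoints.
    Raises :class:`NetworkIntegrityError` for dangling endpoints, duplicate
    ids or nonpositive lengths.
    """
    nodes = nodes.copy().reset_index(drop=True)
    edges = edges.copy().reset_index(drop=True)
    for col in ("node_id", "x", "y"):
        if col not in nodes.columns:
            raise NetworkIntegrityError(f"nodes table missing column '{col}'")
    for col in ("edge_id", "u", "v"):
        if col not in edges.columns:
            raise NetworkIntegrityError(f"edges table missing column '{col}'")
    nodes["node_id"] = nodes["node_id"].astype(int)
    if nodes["node_id"].duplicated().any():
        raise NetworkIntegrityError("duplicate node ids")
    if not np.isfinite(nodes[["x", "y"]].to_numpy(dtype=float)).all():
        raise NetworkIntegrityError("non-finite node coordinates")
    if edges["edge_id"].duplicated().any():
        raise NetworkIntegrityError("duplicate edge ids")
    known = set(nodes["node_id"])
    dangling = set(edges["u"]).union(edges["v"]) - known
    if dangling:
        raise NetworkIntegrityError(f"edges reference unknown nodes: {sorted(dangling)[:5]}")

    xy = {int(r.node_id): (float(r.x), float(r.y)) for r in nodes.itertuples()}
    geoms, lengths, us, vs = [], [], [], []
    for e in edges.itertuples():
        u, v = int(e.u), int(e.v)
        geom = getattr(e, "geometry", None)
        if geom is None or (isinstance(geom, float) and np.isnan(geom)):
            geom = LineString([xy[u], xy[v]])
        if u > v:  # orient from the lower node id
            u, v = v, u
            geom = shapely.reverse(geom)
        length = getattr(e, "length_m", None)
        if length is None or (isinstance(length, float) and np.isnan(length)):
            length = geom.length
        length = float(length)
        if length <= 0:
            raise NetworkIntegrityError(f"edge {e.edge_id}: nonpositive length")
        us.append(u)
        vs.append(v)
        geoms.append(geom)
        lengths.append(length)
    out_edges = pd.DataFrame(
        {
            "edge_id": edges["edge_id"].astype(int),
            "u": us,
            "v": vs,
            "length_m": lengths,
            "geometry": geoms,
        }
    ).sort_values("edge_id", kind="stable").reset_index(drop=True)
    out_nodes = nodes[["node_id", "x", "y"]].sort_values("node_id").reset_index(drop=True)
    return StreetNetwork(nodes=out_nodes, edges=out_edges)


def largest_component(net: StreetNetwork) -> StreetNetwork:
    """Subnetwork induced by the largest connected component.

    Ties are broken in favour of the component containing the smallest
    node id so the result is reproducible.
    """
    if len(net.nodes) == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net.graph))
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    nodes = net.nodes[net.nodes["node_id"].isin(keep)].reset_index(drop=True)
    edges = net.edges[net.edges["u"].isin(keep) & net.edges["v"].isin(keep)].reset_index(drop=True)
    return StreetNetwork(nodes=nodes, edges=edges)


def _sample_offsets(length: float, interval: float) -> np.ndarray:
    if length < interval:
        return np.array([length / 2.0])
    k = int(np.floor((length - _EPS_M) / interval))
    return interval * np.arange(1, k + 1, dtype=float)


def generate_sample_points(
    net: StreetNetwork,
    interval: float = SAMPLE_INTERVAL_M,
    grid: pd.DataFrame | None = None,
    hexes: pd.DataFrame | None = None,
    populated_only: bool = False,
) -> pd.DataFrame:
    """Place residential proxy points along every edge.

    Returns a DataFrame with ``point_id, edge_id, offset_m, x, y`` plus
    ``cell_id``/``hex_id`` lattice memberships when ``grid``/``hexes`` are
    given.  With ``populated_only=True`` (requires ``grid`` with a
    ``population`` column) points in zero-population cells are dropped.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    rows = []
    for e in net.edges.sort_values("edge_id").itertuples():
        for off in _sample_offsets(e.length_m, interval):
            pt = e.geometry.interpolate(off / e.length_m, normalized=True)
            rows.append((e.edge_id, float(off), pt.x, pt.y))
    pts = pd.DataFrame(rows, columns=["edge_id", "offset_m", "x", "y"])
    pts.insert(0, "point_id", np.arange(len(pts)))
    if grid is not None:
        pts["cell_id"] = assign_points(pts, grid, "cell_id")
    if hexes is not None:
        pts["hex_id"] = assign_points(pts, hexes, "hex_id")
    if populated_only:
        if grid is None or "population" not in grid.columns:
            raise ValueError("populated_only requires a grid with populations")
        pop = grid.set_index("cell_id")["population"]
        keep = pts["cell_id"].map(pop).fillna(0.0) > 0
        pts = pts[keep].reset_index(drop=True)
        pts["point_id"] = np.arange(len(pts))
    return pts


def assign_points(points: pd.DataFrame, polygons: pd.DataFrame, id_col: str) -> pd.Series:
    """Assign each point to the polygon covering it (lowest id on boundary ties).

    Points covered by no polygon get ``-1``.
    """
    geoms = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    tree = STRtree(list(polygons["geometry"]))
    pt_idx, poly_idx = tree.query(geoms, predicate="intersects")
    ids = polygons[id_col].to_numpy()
    assigned = np.full(len(points), -1, dtype=int)
    order = np.lexsort((ids[poly_idx], pt_idx))
    # first hit per point after sorting by (point, polygon id) = lowest id
    seen = np.zeros(len(points), dtype=bool)
    for i in order:
        p = pt_idx[i]
        if not seen[p]:
            assigned[p] = ids[poly_idx[i]]
            seen[p] = True
    return pd.Series(assigned, index=points.index, name=id_col)


def _endpoint_distance_maps(net, edge_id, offset_m, cutoff):
    """Dijkstra maps from the two endpoints of the origin edge.

    Returns exact network distances from the mid-edge origin to every node
    within ``cutoff``: the origin splits its edge into two half-edges of
    length ``offset`` and ``L - offset``.
    """
    e = net.edge_record(edge_id)
    L = float(e.length_m)
    if not (0.0 <= offset_m <= L + 1e-9):
        raise ValueError(f"offset {offset_m} outside edge {edge_id} of length {L}")
    g = net.graph
    out = {}
    for anchor, stub in ((int(e.u), float(offset_m)), (int(e.v), L - float(offset_m))):
        if stub > cutoff:
            continue
        dmap = nx.single_source_dijkstra_path_length(
            g, anchor, cutoff=cutoff - stub, weight="length_m"
        )
        for n, d in dmap.items():
            total = d + stub
            if total <= cutoff and (n not in out or total < out[n]):
                out[n] = total
    return out


def shortest_distances(
    net: StreetNetwork, edge_id: int, offset_m: float, cutoff: float
) -> dict:
    """Network distances from a mid-edge origin to all nodes within ``cutoff``.

    The origin sits on edge ``edge_id`` at ``offset_m`` from the lower-id
    endpoint.  Nodes farther than ``cutoff`` are omitted; a zero cutoff
    yields at most the origin edge's endpoints at distance 0.
    """
    if edge_id not in net.edge_by_id.index:
        raise KeyError(f"edge {edge_id} not in network")
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    return _endpoint_distance_maps(net, edge_id, float(offset_m), float(cutoff))


def write_network(net: StreetNetwork, nodes_path, edges_path):
    from .geojson_io import write_geojson

    nodes = net.nodes.copy()
    nodes["geometry"] = [Point(x, y) for x, y in zip(nodes["x"], nodes["y"])]
    write_geojson(nodes, nodes_path)
    write_geojson(net.edges, edges_path)


def read_network(nodes_path, edges_path) -> StreetNetwork:
    from .geojson_io import read_geojson

    nodes = read_geojson(nodes_path).drop(columns=["geometry"])
    edges = read_geojson(edges_path)
    return load_network(nodes, edges)
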