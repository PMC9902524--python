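"""Independent brute-force oracles for the spatial engine.

These deliberately avoid the implementation's code paths (no Dijkstra, no
interval trimming, no STRtree batching): single-source Bellman-Ford style
relaxation for distances, per-metre labelling for reached network length,
exhaustive cell-by-segment intersection tests, and per-destination
minimisation for nearest distances.
"""

from __future__ import annotations

import numpy as np
from shapely.ops import substring


def bellman_ford_from_point(net, edge_id, offset_m, max_iter=None):
    """Distances from a mid-edge origin to every node, by pure relaxation."""
    e = net.edge_by_id.loc[edge_id]
    L = float(e.length_m)
    arcs = [("origin", int(e.u), float(offset_m)), ("origin", int(e.v), L - float(offset_m))]
    for r in net.edges.itertuples():
        arcs.append((int(r.u), int(r.v), float(r.length_m)))
    dist = {"origin": 0.0}
    n = len(net.nodes) + 1
    for _ in range(max_iter or n):
        changed = False
        for a, b, w in arcs:
            for s, t in ((a, b), (b, a)):
                if s in dist and dist[s] + w < dist.get(t, np.inf) - 1e-12:
                    dist[t] = dist[s] + w
                    changed = True
        if not changed:
            break
    dist.pop("origin")
    return dist


def per_metre_reached_length(net, edge_id, offset_m, cutoff, step=1.0):
    """Total reached network length by labelling each metre of each edge."""
    dist = bellman_ford_from_point(net, edge_id, offset_m)
    total = 0.0
    for r in net.edges.itertuples():
        L = float(r.length_m)
        xs = np.arange(step / 2.0, L, step)
        d = np.minimum(
            dist.get(int(r.u), np.inf) + xs, dist.get(int(r.v), np.inf) + (L - xs)
        )
        if r.edge_id == edge_id:
            d = np.minimum(d, np.abs(xs - offset_m))
        total += step * int((d <= cutoff).sum())
    return total


def brute_catchment_cells(net, reached, grid):
    """Exhaustive (cell x segment) intersection test."""
    segs = []
    for r in reached.itertuples():
        geom = net.edge_by_id.loc[r.edge_id, "geometry"]
        segs.append(substring(geom, r.start_m, r.end_m))
    cells = set()
    for c in grid.itertuples():
        for s in segs:
            if c.geometry.intersects(s):
                cells.add(int(c.cell_id))
                break
    return cells


def brute_nearest_distance(net, edge_id, offset_m, layer, cap):
    """Minimum over per-destination shortest distances."""
    dist = bellman_ford_from_point(net, edge_id, offset_m)
    best = np.inf
    for d in layer.itertuples():
        e = net.edge_by_id.loc[d.edge_id]
        cand = min(
            dist.get(int(e.u), np.inf) + float(d.offset_m),
            dist.get(int(e.v), np.inf) + float(e.length_m) - float(d.offset_m),
        )
        if int(d.edge_id) == int(edge_id):
            cand = min(cand, abs(float(d.offset_m) - float(offset_m)))
        best = min(best, cand)
    return min(best, cap), not (best <= cap)
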