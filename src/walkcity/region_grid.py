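"""Study-region definition and the two analysis lattices.

A study region is the intersection of an administrative boundary with an
urban-extent polygon.  Two lattices are draped over it:

* a 250 m axis-aligned square grid carrying residential population counts,
  anchored at the south-west corner of the region bounding box; and
* a 250 m flat-topped hexagon layer whose cells act as "neighbourhoods"
  for aggregation and mapping.  The stated width is the flat-to-flat
  distance, so each hexagon has area ``(sqrt(3)/2) * width**2`` —
  comparable to a grid cell.

Both lattices are deterministic functions of the region bounding box.
All geometry is planar metres; geographic inputs must be projected first
(see :mod:`walkcity.projection`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.validation import explain_validity

SQUARE_CELL_M = 250.0
HEX_WIDTH_M = 250.0
CELL_AREA_KM2 = (SQUARE_CELL_M / 1000.0) ** 2  # 0.0625 km^2


class EmptyRegionError(ValueError):
    """The supplied boundaries do not overlap."""


class ProjectionError(ValueError):
    """Inputs are not in a common planar CRS."""


@dataclass
class RegionBoundary:
    """A valid study-region polygon in planar metric coordinates."""

    polygon: Polygon
    name: str = "region"
    crs_id: str = "local-metric"

    def __post_init__(self):
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise EmptyRegionError(f"region '{self.name}' has no area")
        if not self.polygon.is_valid:
            raise ValueError(
                f"region '{self.name}' polygon invalid: {explain_validity(self.polygon)}"
            )

    @property
    def bounds(self):
        return self.polygon.bounds


def build_study_region(
    admin: Polygon,
    urban_extent: Polygon,
    name: str = "region",
    crs_id: str = "local-metric",
) -> RegionBoundary:
    """Clip an administrative boundary to the urbanised extent.

    Returns the intersection of the two polygons; disjoint inputs raise
    :class:`EmptyRegionError`.
    """
    for label, poly in (("admin", admin), ("urban_extent", urban_extent)):
        if not poly.is_valid:
            raise ValueError(f"{label} polygon invalid: {explain_validity(poly)}")
    region = admin.intersection(urban_extent)
    if region.is_empty or region.area <= 0:
        raise EmptyRegionError("administrative and urban-extent boundaries are disjoint")
    return RegionBoundary(polygon=region, name=name, crs_id=crs_id)


def build_square_grid(region: RegionBoundary, cell_size: float = SQUARE_CELL_M) -> pd.DataFrame:
    """Tile the region with axis-aligned squares.

    Every cell whose square intersects the region is returned, with the
    grid origin at the SW corner of the region bounding box.  Columns:
    ``cell_id`` (row-major from the SW), ``geometry``, ``area_km2`` and a
    ``population`` column initialised to 0.0.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    minx, miny, maxx, maxy = region.bounds
    ncol = max(1, math.ceil((maxx - minx) / cell_size - 1e-9))
    nrow = max(1, math.ceil((maxy - miny) / cell_size - 1e-9))
    cells = []
    cell_id = 0
    poly = region.polygon
    for r in range(nrow):
        for c in range(ncol):
            x0 = minx + c * cell_size
            y0 = miny + r * cell_size
            square = box(x0, y0, x0 + cell_size, y0 + cell_size)
            if square.intersects(poly):
                cells.append(
                    {
                        "cell_id": cell_id,
                        "row": r,
                        "col": c,
                        "geometry": square,
                        "area_km2": (cell_size / 1000.0) ** 2,
                        "population": 0.0,
                    }
                )
            cell_id += 1
    return pd.DataFrame(cells)


def hexagon(cx: float, cy: float, width: float) -> Polygon:
    """Flat-topped hexagon centred at (cx, cy) with flat-to-flat width."""
    r = width / math.sqrt(3.0)  # circumradius
    pts = [
        (cx + r * math.cos(a), cy + r * math.sin(a))
        for a in (np.pi / 180.0) * np.arange(0.0, 360.0, 60.0)
    ]
    return Polygon(pts)


def build_hex_grid(region: RegionBoundary, width: float = HEX_WIDTH_M) -> pd.DataFrame:
    """Tile the region with flat-topped hexagons of given flat-to-flat width.

    Hexagons form a proper tiling (columns spaced 1.5 R apart in x, rows
    ``width`` apart in y, odd columns shifted by half a width); only
    hexagons intersecting the region are kept, with their full (unclipped)
    polygons.  Columns: ``hex_id``, ``geometry``, ``cx``, ``cy``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    r = width / math.sqrt(3.0)
    dx = 1.5 * r
    dy = width
    minx, miny, maxx, maxy = region.bounds
    ncol = math.ceil((maxx - minx) / dx) + 2
    nrow = math.ceil((maxy - miny) / dy) + 2
    hexes = []
    hex_id = 0
    poly = region.polygon
    for c in range(-1, ncol):
        cx = minx + c * dx
        y_off = (width / 2.0) if (c % 2) else 0.0
        for rr in range(-1, nrow):
            cy = miny + rr * dy + y_off
            h = hexagon(cx, cy, width)
            if h.intersects(poly):
                hexes.append({"hex_id": hex_id, "geometry": h, "cx": cx, "cy": cy})
            hex_id += 1
    out = pd.DataFrame(hexes)
    out["hex_id"] = np.arange(len(out))  # dense ids over retained hexes
    return out


def set_population(grid: pd.DataFrame, populations) -> pd.DataFrame:
    """Attach population counts to grid cells (aligned by position or cell_id)."""
    grid = grid.copy()
    populations = np.asarray(populations, dtype=float)
    if populations.shape[0] != len(grid):
        raise ValueError("population vector length does not match grid")
    if (populations < 0).any():
        raise ValueError("cell populations must be nonnegative")
    grid["population"] = populations
    return grid


@dataclass
class _GridReaders:
    """Namespace marker: see read/write helpers below."""


def write_grid(grid: pd.DataFrame, path):
    from .geojson_io import write_geojson

    return write_geojson(grid, path)


def read_grid(path) -> pd.DataFrame:
    from .geojson_io import read_geojson

    df = read_geojson(path)
    required = {"cell_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grid file missing columns: {sorted(missing)}")
    return df
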