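"""Aggregation to hexagon neighbourhoods and city / group summaries.

Point indicators are averaged (unweighted) to the 250 m hexagon layer;
hexagons with no sample points are omitted.  A hexagon is considered to
have large-open-space access when at least half of its member points do.
Hexagon populations are areal-assigned from the 250 m population grid:
each cell's count is split across hexagons in proportion to overlap area.

City-level indicators are population-weighted percentages over hexagons:
``pct = 100 * sum(pop_h * mean_h) / sum(pop_h)`` for each binary access
field, and for the density scenarios the share of population living in
hexagons whose mean density reaches the threshold.  Group summaries
(e.g. by country income class) are unweighted means and population-
denominator SDs over member cities, skipping missing values.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .composite import SCENARIO_A, SCENARIO_B, ThresholdScenario

ACCESS_MEAN_COLUMNS = (
    "access_food_market",
    "access_convenience",
    "access_pt_stop_any",
    "access_pt_stop_30min",
    "access_pt_stop_20min",
    "access_pos_any_entry",
    "access_pos_large_entry",
)


def hex_populations(hexes: pd.DataFrame, grid: pd.DataFrame) -> pd.Series:
    """Areal-weighted assignment of grid-cell populations to hexagons.

    Conserves total population over hexagons covering the gridded area.
    """
    hex_geoms = list(hexes["geometry"])
    tree = STRtree(hex_geoms)
    hex_ids = hexes["hex_id"].to_numpy()
    pops = np.zeros(len(hexes), dtype=float)
    for cell in grid.itertuples():
        if cell.population <= 0:
            continue
        idx = tree.query(cell.geometry, predicate="intersects")
        if len(idx) == 0:
            continue
        areas = np.array([cell.geometry.intersection(hex_geoms[i]).area for i in idx])
        total = areas.sum()
        if total <= 0:
            continue
        pops[idx] += cell.population * areas / total
    return pd.Series(pops, index=hex_ids, name="population")


def aggregate_to_hex(
    points: pd.DataFrame,
    hexes: pd.DataFrame,
    grid: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Unweighted mean of every numeric point field per hexagon.

    Adds ``n_points``, the binary ``pos_large_access`` (mean of member
    points' large-open-space scores >= 0.5) and, when ``grid`` is given,
    the areal-assigned hexagon ``population``.
    """
    if "hex_id" not in points.columns:
        raise ValueError("points need a hex_id column (assign with generate_sample_points)")
    pts = points[points["hex_id"] >= 0]
    numeric = pts.select_dtypes(include=[np.number]).drop(
        columns=["point_id", "edge_id", "offset_m", "cell_id"], errors="ignore"
    )
    summary = numeric.groupby("hex_id").mean()
    summary.insert(0, "n_points", pts.groupby("hex_id").size())
    if "access_pos_large_entry" in summary.columns:
        summary["pos_large_access"] = hex_pos_access(summary["access_pos_large_entry"])
    if grid is not None:
        pop = hex_populations(hexes, grid)
        summary["population"] = pop.reindex(summary.index).fillna(0.0)
    return summary.reset_index()


def hex_pos_access(mean_binary) -> np.ndarray:
    """Hex-level open-space access: 1 iff at least half the points have it."""
    return (np.asarray(mean_binary, dtype=float) >= 0.5).astype(int)


def city_percentages(
    hex_summary: pd.DataFrame,
    scenarios: tuple[ThresholdScenario, ...] = (SCENARIO_A, SCENARIO_B),
    name: str = "city",
    income_group: str | None = None,
) -> dict:
    """Population-weighted city indicator percentages over hexagons.

    Access percentages weight each hexagon's mean binary score by its
    population; scenario exposure is the population share of hexagons
    whose mean density reaches or exceeds the threshold.  Indicators whose
    column is absent (e.g. no transit schedule) come out as NaN.
    """
    pop = hex_summary["population"].to_numpy(dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError("total hexagon population is zero")
    out = {"city": name}
    if income_group is not None:
        out["income_group"] = income_group
    for col in ACCESS_MEAN_COLUMNS:
        key = "pct_" + col.removeprefix("access_")
        if col in hex_summary.columns and hex_summary[col].notna().any():
            out[key] = float(100.0 * (pop * hex_summary[col].to_numpy(dtype=float)).sum() / total)
        else:
            out[key] = np.nan
    for sc in scenarios:
        meets_pop = hex_summary["pop_density"].to_numpy(dtype=float) >= sc.pop_density_threshold
        meets_int = hex_summary["int_density"].to_numpy(dtype=float) >= sc.int_density_threshold
        out[f"pct_pop_density_{sc.name}"] = float(100.0 * pop[meets_pop].sum() / total)
        out[f"pct_int_density_{sc.name}"] = float(100.0 * pop[meets_int].sum() / total)
    return out


def group_summary(
    cities: pd.DataFrame,
    grouping: str = "income_group",
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean and SD (n denominator) per indicator over member cities.

    Missing values are excluded per indicator, so a city without transit
    data simply does not enter the transit column's mean.  A ``Total`` row
    over all cities is appended.
    """
    if value_columns is None:
        value_columns = [
            c for c in cities.columns if cities[c].dtype.kind in "fi" and c != grouping
        ]
    rows = []

    def _row(label, frame):
        rec = {"group": label, "n_cities": len(frame)}
        for c in value_columns:
            vals = frame[c].dropna().to_numpy(dtype=float)
            rec[f"{c}_mean"] = vals.mean() if vals.size else np.nan
            rec[f"{c}_sd"] = vals.std(ddof=0) if vals.size else np.nan
        return rec

    for label, frame in cities.groupby(grouping, sort=True):
        if len(frame) == 0:
            warnings.warn(f"group {label!r} empty; omitted")
            continue
        rows.append(_row(str(label), frame))
    rows.append(_row("Total", cities))
    return pd.DataFrame(rows)


def export_outputs(
    out_dir,
    points: pd.DataFrame | None = None,
    hex_summary: pd.DataFrame | None = None,
    hexes: pd.DataFrame | None = None,
    city: dict | None = None,
    groups: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict:
    """Write run outputs: per-point CSV, hex GeoJSON, city/group CSVs, manifest."""
    from .geojson_io import write_geojson

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if points is not None:
        p = out_dir / "point_indicators.csv"
        points.to_csv(p, index=False, float_format="%.6f")
        written["points"] = p
    if hex_summary is not None:
        p = out_dir / "hex_summary.csv"
        hex_summary.to_csv(p, index=False, float_format="%.6f")
        written["hex_summary"] = p
        if hexes is not None:
            merged = hexes.merge(hex_summary, on="hex_id", how="inner")
            p = out_dir / "hex_summary.geojson"
            write_geojson(merged, p)
            written["hex_geojson"] = p
    if city is not None:
        p = out_dir / "city_summary.csv"
        pd.DataFrame([city]).to_csv(p, index=False, float_format="%.6f")
        written["city"] = p
    if groups is not None:
        p = out_dir / "group_summary.csv"
        groups.to_csv(p, index=False, float_format="%.6f")
        written["groups"] = p
    if manifest is not None:
        p = out_dir / "run_manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        written["manifest"] = p
    return written
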