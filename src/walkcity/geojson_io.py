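"""Read and write GeoJSON FeatureCollections as pandas DataFrames.

Tables carry shapely geometries in a ``geometry`` object column; all other
columns round-trip as feature properties.  Coordinates are written with
millimetre precision so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

_COORD_DECIMALS = 3


def _round_geometry(geom):
    return shapely.set_precision(geom, 10 ** (-_COORD_DECIMALS), mode="pointwise")


def dataframe_to_feature_collection(df: pd.DataFrame, geometry_col: str = "geometry") -> dict:
    features = []
    for _, row in df.iterrows():
        props = {}
        for col, val in row.items():
            if col == geometry_col:
                continue
            if isinstance(val, (pd.Timestamp,)):
                val = str(val)
            elif pd.isna(val):
                val = None
            elif hasattr(val, "item"):  # numpy scalar
                val = val.item()
            props[col] = val
        geom = mapping(_round_geometry(row[geometry_col]))
        features.append({"type": "Feature", "properties": props, "geometry": geom})
    return {"type": "FeatureCollection", "features": features}


def write_geojson(df: pd.DataFrame, path, geometry_col: str = "geometry") -> Path:
    path = Path(path)
    fc = dataframe_to_feature_collection(df, geometry_col)
    path.write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")
    return path


def read_geojson(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    records = []
    geoms = []
    for feat in payload["features"]:
        records.append(feat.get("properties") or {})
        geoms.append(shape(feat["geometry"]))
    df = pd.DataFrame.from_records(records)
    df["geometry"] = geoms
    return df
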