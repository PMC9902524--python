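"""Composite point-level indicators: daily living, walkability, threshold flags.

The daily living score (0-3) counts amenity types within 500 m network
distance: healthy food market, convenience store, any public transport
stop.  The walkability index sums equal-weighted z-scores of population
density, street intersection density, and daily living score; the z-scores
can be standardised against the city's own points (within-city) or against
the pooled records of all cities under comparison (between-city), so a
walkability of zero marks the reference-set average.

Scenario threshold flags mark whether a record's densities reach or exceed
(>=) evidence-based targets: scenario A pairs with an 80% probability of
walking for transport, scenario B with WHO's goal of a >= 15% relative
reduction in insufficient physical activity.  The default thresholds are
the lower bounds of the published 95% CIs for each scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ThresholdScenario:
    name: str
    pop_density_threshold: float  # persons / km^2
    int_density_threshold: float  # intersections / km^2

    def __post_init__(self):
        if self.pop_density_threshold <= 0 or self.int_density_threshold <= 0:
            raise ValueError("scenario thresholds must be positive")


# lower bounds of the published 95% CIs for each scenario
SCENARIO_A = ThresholdScenario("A", pop_density_threshold=4790.0, int_density_threshold=90.0)
SCENARIO_B = ThresholdScenario("B", pop_density_threshold=5677.0, int_density_threshold=106.0)


def daily_living_score(access_food, access_convenience, access_pt_any):
    """Sum of the three 500 m binary access scores (0-3)."""
    arrs = [np.asarray(a) for a in (access_food, access_convenience, access_pt_any)]
    for a in arrs:
        if not np.isin(a, (0, 1)).all():
            raise ValueError("daily living inputs must be binary 0/1")
    total = arrs[0] + arrs[1] + arrs[2]
    if np.isscalar(access_food):
        return int(total)
    return total


def standardise(values, reference=None) -> np.ndarray:
    """Z-scores ``(x - mean_ref) / sd_ref`` with population (n) denominator sd.

    ``reference`` defaults to ``values`` itself (within-city use); pass the
    pooled all-cities records for between-city standardisation.  A
    zero-variance reference yields all-zero z-scores with a warning.
    """
    x = np.asarray(values, dtype=float)
    ref = x if reference is None else np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference set needs at least 2 values")
    mean = ref.mean()
    sd = ref.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance in reference set: z-scores set to 0")
        return np.zeros_like(x)
    return (x - mean) / sd


def walkability(z_pop, z_int, z_daily) -> np.ndarray:
    """Equal-weighted sum of the three standardised components."""
    return np.asarray(z_pop, dtype=float) + np.asarray(z_int, dtype=float) + np.asarray(z_daily, dtype=float)


def scenario_flags(pop_density, int_density, scenario: ThresholdScenario):
    """(meets_pop, meets_int): densities reaching or exceeding the thresholds."""
    meets_pop = (np.asarray(pop_density, dtype=float) >= scenario.pop_density_threshold).astype(int)
    meets_int = (np.asarray(int_density, dtype=float) >= scenario.int_density_threshold).astype(int)
    if np.isscalar(pop_density):
        return int(meets_pop), int(meets_int)
    return meets_pop, meets_int


ACCESS_COLUMNS = (
    "access_food_market",
    "access_convenience",
    "access_pt_stop_any",
    "access_pt_stop_30min",
    "access_pt_stop_20min",
    "access_pos_any_entry",
    "access_pos_large_entry",
)


def point_indicators(catchments: pd.DataFrame, access_wide: pd.DataFrame) -> pd.DataFrame:
    """Join catchment densities with access scores; add the daily living score.

    Missing access classes (e.g. no GTFS feed for the city) stay absent
    and propagate as nulls downstream.
    """
    points = catchments.merge(access_wide, on="point_id", how="inner")
    points["daily_living"] = daily_living_score(
        points["access_food_market"],
        points["access_convenience"],
        points["access_pt_stop_any"],
    )
    return points


def add_walkability(
    points: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    column: str = "walkability_within",
) -> pd.DataFrame:
    """Attach a walkability column standardised against ``reference``.

    ``reference`` defaults to ``points`` itself (within-city).  For
    between-city use pass the pooled records of all cities and name the
    column ``walkability_between``.
    """
    ref = points if reference is None else reference
    out = points.copy()
    z = [
        standardise(points[c], ref[c]) for c in ("pop_density", "int_density", "daily_living")
    ]
    out[column] = walkability(*z)
    return out
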