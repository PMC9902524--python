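"""Walkable catchments: reachable network, grid footprint, densities.

Every 30 m sample point gets a 1000 m walkable catchment — the grid
cells touched by the street network reachable within 1000 m — and from
it a population density and a street intersection density.
"""

from walkcity import CitySpec, compute_catchments, generate_sample_points
from walkcity.synthetic_city import generate_city

city = generate_city(CitySpec(seed=3, extent_m=1500.0, pop_total=15_000))
points = generate_sample_points(city.net, interval=30.0, grid=city.grid, populated_only=True)
print(f"{len(points)} sample points along {city.net.total_length_m/1000:.1f} km of streets")

catchments = compute_catchments(city.net, points.head(50), city.grid, cutoff=1000.0)
row = catchments.iloc[0]
print(f"first point: {row.n_cells:.0f} cells = {row.area_km2:.3f} km2, "
      f"{row.population:.0f} residents, {row.intersections:.0f} intersections")
print(f"  -> {row.pop_density:.0f} persons/km2, {row.int_density:.1f} intersections/km2")
print(f"mean over 50 points: {catchments.pop_density.mean():.0f} persons/km2, "
      f"{catchments.int_density.mean():.1f} intersections/km2")
print("These two densities are two of the three walkability components;")
print("larger values mean more people and more route choice within a short walk.")
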