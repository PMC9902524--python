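"""Bundled benchmark tables: published indicator estimates for 25 cities.

Two small reference tables ship with the package so group-level summaries
can be exercised and worked examples run without any spatial inputs:

* ``city_access_benchmarks.csv`` — population percentages with 500 m
  access per amenity class and transport-sector PM2.5 emissions, for 25
  cities in 19 countries, with country income grouping.  Cities where a
  class could not be measured (e.g. no machine-readable transit schedule)
  have empty cells.
* ``city_threshold_benchmarks.csv`` — population percentages living in
  neighbourhoods meeting the scenario A/B population- and
  intersection-density thresholds for the same cities.

Values are as printed (one decimal, percent scale).
"""

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_city_access_benchmarks() -> pd.DataFrame:
    """25-city amenity access percentages and PM2.5 passthrough values."""
    return _read("city_access_benchmarks.csv")


def load_city_threshold_benchmarks() -> pd.DataFrame:
    """25-city scenario A/B density threshold exposure percentages."""
    return _read("city_threshold_benchmarks.csv")
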