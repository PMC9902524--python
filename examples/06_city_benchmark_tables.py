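"""Group summaries over the bundled 25-city benchmark tables.

The package ships published city-level indicator estimates for 25 cities
in 19 countries.  ``group_summary`` reproduces the income-group and
overall summary rows: unweighted means with population-denominator SDs,
skipping cities where an indicator could not be measured.
"""

from walkcity.data import load_city_access_benchmarks, load_city_threshold_benchmarks
from walkcity.summarise import group_summary

access = load_city_access_benchmarks()
groups = group_summary(access, grouping="income_group").set_index("group")

print("Population % with 500 m access to a healthy food market:")
for g in ("middle", "high", "Total"):
    row = groups.loc[g]
    print(f"  {g:>6s}: {row['pct_food_market_mean']:.1f}% (SD {row['pct_food_market_sd']:.1f}), "
          f"n={row['n_cities']:.0f}")

eu = group_summary(access, grouping="region").set_index("group").loc["Europe"]
print(f"European cities average {eu['pct_food_market_mean']:.0f}% food access — the highest region.")

pm = groups[["pm25_transport_tpa_mean"]]
print(f"Transport PM2.5: middle-income mean {pm.loc['middle'].iloc[0]:.1f} t/yr vs "
      f"high-income {pm.loc['high'].iloc[0]:.1f} t/yr (~5x higher).")

thresh = group_summary(load_city_threshold_benchmarks(), grouping="income_group").set_index("group")
print("Population % in neighbourhoods meeting the scenario A population-density")
print(f"threshold: middle-income {thresh.loc['middle','pct_pop_density_A_mean']:.1f}%, "
      f"high-income {thresh.loc['high','pct_pop_density_A_mean']:.1f}%.")
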