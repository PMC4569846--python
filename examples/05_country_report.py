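"""Country-level completeness, gap shares and the wealth regression.

Which countries hold the missing species-cell combinations, and does
national wealth explain who has complete inventories?
"""

import biogaps as bg

world = bg.generate_world(bg.WorldConfig(seed=1))
inv = bg.build_inventory(world.ranges, world.records, world.grid, grains=[1])

summary = bg.country_completeness(inv, world.country_of_cell, world.grid)
summary["missing_share"] = bg.missing_share(summary)
summary = summary.join(world.country_table[["gdp_ppp"]])
print(summary.round(3).sort_values("missing_share", ascending=False).to_string())
print(f"\nmissing shares sum to {summary['missing_share'].sum():.3f} "
      "(each country's slice of the global gap)")

w = bg.wealth_regression(summary["completeness"], summary["gdp_ppp"])
print(f"completeness ~ log10(GDP per capita): r2 = {w['r2']:.2f}, "
      f"slope = {w['slope']:.2f} per decade of wealth, p = {w['p']:.2e} "
      f"({w['n']} countries)")
# In the generated worlds wealth correlates with research funding, the
# strongest true driver, so a substantial r2 is expected.
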