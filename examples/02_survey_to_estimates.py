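"""Simulate a small survey programme and turn unit counts into estimates.

Generates NB2 unit-level counts for one county over the default survey
calendar, then applies Jolly Method 2 to every (survey, species) to produce
the estimate table the trend model consumes.
"""

from rangetrends import jolly, simulate

cfg = simulate.default_scenario(seed=42, county_areas={"Solo": 9000.0})
units = simulate.simulate_units(cfg)
design = units[["county", "date", "zone_area_km2", "total_units_N"]].drop_duplicates()

estimates = jolly.estimate_all(units, design)
print(estimates.head(8).to_string(index=False))
print(f"\n{len(estimates)} estimates "
      f"({estimates.species.nunique()} species x {estimates.date.nunique()} surveys)")
# Each row is one species in one survey: the design-based population total,
# its standard error and the sample density. Compare the zebra estimates
# against the generating truth (1.2 animals/km^2 declining at 2.88%/yr).
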