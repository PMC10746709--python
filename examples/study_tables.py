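"""Headline aggregates recomputed from the packaged per-site tables.

Loads the transcribed site x species stock table and the site table of
areas, accretion and burial rates, and recomputes the study-level
summaries (means, ranges, regional tonnages).
"""

from marshcarbon import aggregate

s = aggregate.study_summaries()

print(f"sites x species stock records: {s['stock_total_mean'].n}")
print(f"mean total OC stock (table rows): {s['stock_total_mean'].mean:.2f} Mg OC/ha")
print(f"mean belowground OC stock:        {s['stock_belowground_mean'].mean:.2f} Mg OC/ha")
print(f"accretion rate: mean {s['sar'].mean:.2f} mm/yr, "
      f"range {s['sar'].min:.2f}-{s['sar'].max:.2f} (n = {s['sar'].n})")
print(f"OC burial rate: mean {s['burial'].mean:.2f} g OC/m^2/yr, "
      f"range {s['burial'].min:.2f}-{s['burial'].max:.2f}")
print(f"regional belowground OC: {s['belowground_tons']:,.0f} t "
      f"of {s['total_tons']:,.0f} t total "
      f"({100 * s['belowground_tons'] / s['total_tons']:.0f}%)")
print(f"annual regional burial potential: {s['annual_burial_tons']:,.1f} t OC/yr")
print("-> one undated site is excluded from rate summaries (absent, not zero)")
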