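"""Simulate a two-group flax cohort and census its polymorphisms.

Builds a synthetic cohort of 79 fiber-flax and 112 linseed varieties with
low-coverage read support, applies the four-read support filter, and
tallies polymorphism counts and per-kb densities per gene and family.
"""

from flaxscreen import (
    CohortSimConfig,
    census,
    family_totals,
    filter_supported,
    simulate_cohort,
    simulate_read_support,
)
from flaxscreen.census import census_frame

cfg = CohortSimConfig(seed=42)
manifest, panel, truth = simulate_cohort(cfg)
table = simulate_read_support(truth, cfg)
print(f"cohort: {manifest.count('fiber')} fiber + {manifest.count('linseed')} linseed "
      f"varieties; {len(table)} variants over {len(panel)} genes")

supported = filter_supported(table, min_alt_reads=4)
print(f"support filter (>=4 alt reads in some sample): "
      f"{len(supported)} of {len(table)} variants retained")

records = census(supported, panel)
df = census_frame(records)
print("\nmost polymorphic genes (per kb of gene + flanks):")
print(df.nlargest(5, "density_per_kb").to_string(index=False))
print("\nfamily totals:", family_totals(records))
# densities are supported variants per kb of analysis region
# (gene body + 500 bp flanks on both sides)
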