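"""Rediscover the look-ahead heading-rate law from record data.

Records pair the 24 look-ahead updraft differences dwo(alpha, d) with
the next second's heading rate.  The discovery procedure bins each
pair's dwo between its 1st and 99th percentile, equalizes bin occupancy
by subsampling, takes median heading rates per bin, fits a line per
pair, and collapses the 24 slopes onto one coefficient c_omega via
their arc lengths d * alpha.
"""

from soarflight import discover_relation
from soarflight.synthetic import make_discovery_records

records = make_discovery_records(100_000, c_omega=30.0, seed=7)
rel = discover_relation(records, seed=8)

print(f"records: {len(records)}")
print(f"recovered c_omega: {rel.c_omega:.2f} (generating value 30)")
print("\nper-pair slopes (deg/s per m/s) and their collapse:")
print(rel.slopes[["alpha", "d", "slope", "normalized_slope"]].to_string(index=False))

# "normalized_slope" multiplies each slope by its arc length d * alpha_rad;
# the values agreeing across all 24 pairs is the collapse that makes one
# coefficient sufficient for any updraft field.
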