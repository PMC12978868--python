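"""Build an orographic updraft field over ridge terrain.

A north-south ridge in a westerly wind deflects air upward on its
windward (west) face.  The field is w * sin(slope) * cos(wind - aspect),
clipped at zero and smoothed with a 250-m Gaussian kernel.
"""

import numpy as np

from soarflight import WindField, build_updraft_field
from soarflight.synthetic import Ridge, SyntheticScenario, make_terrain

scenario = SyntheticScenario(
    domain_size=(4000.0, 4000.0), spacing=10.0,
    ridges=(Ridge(center_x=2000.0, height=250.0, width=350.0),),
    noise_amplitude=0.0,
)
terrain = make_terrain(scenario)
wind = WindField(speed=10.0, direction=270.0)  # from the west
updraft = build_updraft_field(terrain, wind, radius=250.0)

crest_ix = terrain.elevation[200].argmax()
peak_iy, peak_ix = np.unravel_index(updraft.values.argmax(), updraft.values.shape)
print(f"max slope: {terrain.slope.max():.1f} deg")
print(f"max updraft: {updraft.values.max():.2f} m/s "
      f"at x = {terrain.x_coords[peak_ix]:.0f} m (crest at {terrain.x_coords[crest_ix]:.0f} m)")
print(f"updraft on lee side (x = 2600 m): {updraft.sample(2600.0, 2000.0):.2f} m/s")

# The strongest lift sits on the windward slope west of the crest; the lee
# side is near zero because downdrafts are clipped before smoothing.
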