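"""Join smoothed motion states with terrain and wind covariates.

Each 1-s state is annotated with: ground elevation under the bird
(bilinear on the DEM lattice), altitude above ground level (AGL; kept
when negative — DEM and GPS errors make that possible near ridges, and
those records remain in the rotor-swept zone), wind speed and direction
at 80 m AGL (bilinear in space, linear in time; altitude variation not
modelled), the smoothed orographic updraft sampled at the position, and
the tailwind/crosswind components relative to the bird's heading.

The rotor-swept-zone flag marks records with AGL strictly below 200 m,
the altitude band where turbine blades operate and where the movement
model is calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import OutOfDomainError
from .terrain import TerrainGrid, UpdraftField, WindField, bilinear_sample, wind_components

__all__ = ["annotate_track", "RSZ_CEILING"]

#: rotor-swept-zone ceiling, m AGL (strict upper bound)
RSZ_CEILING = 200.0


def annotate_track(
    states: pd.DataFrame,
    terrain: TerrainGrid,
    wind: WindField,
    updraft: UpdraftField,
) -> pd.DataFrame:
    """Annotate a derived-motion state table with environmental covariates.

    ``states`` must carry px/py/pz/heading (see
    :func:`soarflight.smoother.derive_motion`).  All points must lie
    inside the terrain grid; an :class:`OutOfDomainError` listing the
    offending row indices is raised otherwise.  Annotation is pure:
    identical inputs give bit-identical output.
    """
    px = states["px"].to_numpy(dtype=float)
    py = states["py"].to_numpy(dtype=float)
    pz = states["pz"].to_numpy(dtype=float)
    t = states["t"].to_numpy(dtype=float)

    inside = terrain.contains(px, py)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise OutOfDomainError(
            f"{bad.size} track point(s) outside the terrain grid", indices=bad
        )

    hg = bilinear_sample(terrain.elevation, px, py, terrain.origin_xy, terrain.spacing)
    h_agl = pz - hg

    if wind.is_gridded:
        w = np.empty(len(states))
        phi_w = np.empty(len(states))
        for i in range(len(states)):
            w[i], phi_w[i] = wind.sample(px[i], py[i], t[i])
    else:
        w, phi_w = wind.sample(px, py)

    wo = updraft.sample(px, py)
    wt, wc = wind_components(w, phi_w, states["heading"].to_numpy(dtype=float))

    out = states.copy()
    out["hg"] = hg
    out["h_agl"] = h_agl
    out["w"] = w
    out["phi_w"] = phi_w
    out["wo"] = wo
    out["wt"] = wt
    out["wc"] = wc
    out["rsz"] = h_agl < RSZ_CEILING
    return out
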