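"""End-to-end orchestration: raw fixes to calibration-ready tracks.

Chains the preprocessing, smoothing, annotation, and look-ahead steps so
calibration experiments and the command-line tool share one code path.
"""

from __future__ import annotations

import pandas as pd

from .annotate import annotate_track
from .lookahead import LookaheadSpec, add_lambda
from .simulate import Environment
from .smoother import smooth_and_derive
from .telemetry import preprocess

__all__ = ["process_fix_tables"]


def process_fix_tables(
    fix_tables: list[pd.DataFrame],
    env: Environment,
    projection: str = "identity",
    obs_noise: dict | None = None,
    process_noise: dict | None = None,
    lookahead_spec: LookaheadSpec | None = None,
) -> list[pd.DataFrame]:
    """Raw fix tables -> annotated 1-s tracks with the look-ahead covariate.

    Each input table is one individual's record (t, lon, lat, alt_msl).
    Steps: project, quality-filter, segment into tracks, Kalman/RTS
    smooth to 1 s, derive speed/heading/heading-rate, annotate terrain
    and wind covariates, and attach the collapsed look-ahead covariate.
    Tracks that wander off the terrain grid are skipped.
    """
    from .errors import OutOfDomainError

    spec = lookahead_spec or env.lookahead
    out = []
    for fixes in fix_tables:
        for track in preprocess(fixes, projection=projection):
            states = smooth_and_derive(
                track, obs_noise=obs_noise, process_noise=process_noise
            )
            try:
                ann = annotate_track(states, env.terrain, env.wind, env.updraft)
            except OutOfDomainError:
                continue
            out.append(add_lambda(ann, env.updraft, spec))
    return out
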