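# soarflight

Fine-scale movement modelling of low-altitude soaring flight, for
predicting where a soaring bird — think golden eagle working a ridge —
will be over the next one to three minutes, and which wind-turbine rotors
it is most likely to meet on the way.

Soaring raptors subsidize low-altitude flight with orographic updrafts:
wind deflected upward by sloped terrain. That places them in the
**rotor-swept zone** (RSZ, below 200 m above ground), where turbine
blades operate. Automated curtailment systems detect an approaching bird
and must decide within seconds which turbines to slow; today they
extrapolate the detection in a straight line. `soarflight` implements a
data-driven alternative: a discrete-time Markov movement model whose
predictors respond to the updraft field the bird can *see ahead of
itself*, calibrated from GPS telemetry and run forward as a stochastic
path ensemble to produce a time-explicit collision-risk map.

The package is aimed at quantitative movement ecologists and
wind-wildlife researchers. Everything is importable from Python
(`examples/` holds one narrative script per capability) and the same
stages are exposed as a thin `soarflight` command-line tool.

## The model

Per-second motion states are modelled through three predictors —
vertical speed $v_z$, horizontal speed $v_h$, and heading rate $\omega$
(deg/s, clockwise) — each following a linear Markov update with
state-dependent noise:

$$y_{k+1} = \sum_j \beta_j^{\text{mean}}\,\psi_{j,k} + \epsilon_k,\qquad
\epsilon_k \sim \mathcal N\!\Big(0,\ \big(\textstyle\sum_j \beta_j^{\text{err}}\,\psi_{j,k}\big)^2\Big)$$

with covariates $\psi_k$: crosswind $w_c$, tailwind $w_t$, orographic
updraft $w_o = \max(0,\ w \sin\phi_s \cos(\phi_w-\phi_a))$, altitude AGL
$h_{agl}$, the predictor's own values 5/10/30 s earlier, and — for the
heading rate only — a **look-ahead covariate**. That covariate comes from
28 points at bearings $\theta + \alpha$, $\alpha \in \{0,\pm15,\pm30,\pm60\}^\circ$
and ranges $d \in \{50,100,200,300\}$ m: the updraft surplus at each
off-axis point, normalized by arc length,

$$\omega \;=\; c_\omega\, \frac{\Delta w_o(\alpha,d)}{d\,\alpha},$$

an empirical law discovered from binned medians of heading rate whose 24
per-pair slopes collapse onto the single coefficient $c_\omega$. Paths
are integrated at $T = 1$ s:
$(p_x, p_y, p_z, \theta) \mathrel{+}= T\,(v_h\sin\theta,\ v_h\cos\theta,\ v_z,\ \omega)$.

Upstream of the model, raw variable-interval GPS fixes (3 s–15 min) are
projected to planar meters, quality-filtered, segmented into tracks
(gap ≤ 10 s, duration > 5 min, ≥ 50 fixes), and resampled to exact 1-s
states by a per-axis constant-acceleration Kalman filter with an RTS
smoother that respects GPS noise (≈2 m horizontal, 6 m vertical).
Downstream, simulated ensembles are scored against reference tracks by
the radial-distance distribution per time lag (reported in meters and in
130-m rotor diameters D) against a constant-velocity baseline, and
summarized as risk maps: smoothed, normalized presence densities of
RSZ flight.

The eagle telemetry such models are calibrated on is not publicly
distributable, so the package ships a first-class synthetic module:
parametric ridge terrain, a truth movement model with known weights, and
a GPS degradation process matching the sampling statistics of
solar-powered tracking units on large raptors.
Every recovery experiment therefore has a known answer.

## Worked example

```bash
python examples/full_synthetic_study.py
```

runs the whole loop — 200 truth tracks from a known model
($c_\omega = 30$), GPS degradation, preprocessing, smoothing,
annotation, law discovery, calibration, validation — and prints:

```
annotated tracks: 64, calibration rows: 18737, look-ahead records: 20588
truth c_omega:       30.0
rediscovered c_omega: 30.5 (2% off)
calibrated look-ahead weight: 51.9
median 3-min prediction error: model 1.9 D, constant-velocity baseline 2.2 D (D = 130 m rotor diameter, over 20 windows)
```

Reading it: of 200 generated tracks, 64 survive the segmentation rules
after GPS degradation; the look-ahead law is rediscovered from ~21k
records within 2% of the generating coefficient for this realization
(recovery through the GPS observation process varies noticeably between
realizations — see `docs/methods.md`); and at three minutes the
calibrated model places the bird a median 1.9 rotor diameters from the
true position, against 2.2 D for the straight-line extrapolation a
curtailment system would use today.

Other examples: `updraft_field.py` (terrain → updraft field),
`smooth_gps_track.py` (noisy fixes → 1-s motion states),
`discover_lookahead_law.py` (the binning/collapse procedure),
`simulate_and_map_risk.py` (path ensembles → risk maps).

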