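# Methods

This note documents the models, the numerical choices, and the design
decisions behind `soarflight`, in the order data flows through the
package. It also records what the synthetic study can and cannot show
about real telemetry.

## Telemetry preprocessing

Raw fixes are (timestamp, longitude, latitude, altitude MSL) per
individual. Geographic coordinates are projected to planar meters with
the North America Albers Equal Area Conic projection (GRS80; standard
parallels 20°/60° N, origin 40° N 96° W), implemented from the standard
ellipsoidal closed forms with a Newton inverse; synthetic data is
already planar and uses an identity projection. Quality filters then
remove (a) fixes whose finite-difference horizontal speed is below
1 m/s (mostly perched birds; the first fix uses a forward difference so
an entirely stationary record empties) and (b) the central fix of any
triple whose vertical-speed change reaches 6 m/s² (altitude glitches).
Because each removal changes neighbouring finite differences, the
filters iterate to a fixed point, which makes filtering idempotent.
Surviving fixes are segmented at time gaps above 10 s, and segments are
kept only with duration strictly over 5 min and at least 50 fixes.

## Kalman/RTS smoothing to 1-s states

Each planar axis is filtered independently with a constant-acceleration
(white-noise-jerk) state space, position-observed, with exact
discretization of the transition over each inter-fix gap; a
fixed-interval Rauch–Tung–Striebel pass then conditions every state on
the whole track. States are emitted on a uniform 1-s grid (prediction
nodes between observations). The smoothed means coincide with the batch
linear-Gaussian least-squares solution; the test suite verifies this to
1e-6 relative error against an independently coded stacked solve.

Defaults: observation noise 2 m horizontal / 6 m vertical (1-sigma);
diffuse prior (100 m, 20 m/s, 5 m/s²) anchored at the first fix with a
finite-difference velocity seed; Joseph-form updates for numerical
symmetry.

Process noise (jerk spectral density, m² s⁻⁵) is the one genuinely open
smoother parameter. The horizontal default q = 0.2 minimizes
state-estimation RMSE on the synthetic soaring benchmark. The vertical
default is q = 0.5 — deliberately *larger* than RMSE-optimal. With 6-m
vertical noise at ~6-s spacing, an RMSE-optimal vertical smoother
produces a near-deterministic, locally-quadratic $v_z$ series; the lag
regression of the movement model then finds extrapolation-like
coefficient pairs (large positive at lag 5, large negative at lag 10)
that are dynamically **unstable** when the calibrated model is run
forward — simulated vertical speed diverges. Inflating the vertical
process noise keeps enough innovation in the smoothed series for the
fitted dynamics to remain stable. Both values satisfy the sanity bound
that ~95% of smoothed accelerations on calibration-like data stay
within ±6 m/s².

Derived motion: $v_h=\sqrt{v_x^2+v_y^2}$; heading
$\theta=\operatorname{atan2}(v_x,v_y)$ (compass convention; the
two-argument form resolves the quadrant ambiguity of the ratio formula);
heading rate $\omega=(a_x v_y-a_y v_x)/v_h^2$, exact for circular
motion, undefined (NaN) where $v_h=0$.

## Environmental annotation

Slope and aspect come from central finite differences of the elevation
raster (one-sided at edges); aspect is the downhill facing direction,
0° = north, set to 0 with a flag on exactly flat cells (inert, since
sin 0 = 0 in the updraft formula). The orographic updraft
$w_o = w\sin\phi_s\cos(\phi_w-\phi_a)$ is clipped at zero nodewise and
*then* smoothed with a Gaussian kernel whose standard deviation is
250 m divided by the grid spacing (the kernel-radius convention adopted
here); the smoothed field, not the pointwise formula, defines the
covariate everywhere downstream. Wind is sampled bilinearly in space and
linearly in time (shorter-arc interpolation for direction) at 80 m AGL
regardless of the bird's altitude; altitude dependence of wind and
updraft is out of scope. Tailwind/crosswind follow
$w_t = w\cos(\theta-\phi_w)$, $w_c = w\sin(\theta-\phi_w)$, applied
literally (so $w_t = w$ when flying *toward* the wind's origin under the
meteorological "from" convention; the identity
$w_t^2+w_c^2=w^2$ holds exactly). Altitude AGL may be negative near
ridges — DEM interpolation plus GPS error make that physical reality for
ridge-hugging flight — and such records are retained and counted inside
the rotor-swept zone (strictly below 200 m AGL).

## The look-ahead law

The look-ahead lattice has 28 points (7 bearings × 4 ranges); the 24
off-axis updraft differences $\Delta w_o(\alpha,d)$ are normalized by
their arc lengths $d\,\alpha_{\text{rad}}$ and averaged with equal
weight into the simulation-time covariate $\Lambda$ (equal weighting is
the aggregation consistent with the observed collapse; the law itself
does not fix it). Discovery proceeds per pair: equal-width bins of
$\Delta w_o$ between its 1st and 99th percentiles (bin count reduced
with a warning if any bin is empty), equal-occupancy random subsampling
within bins, median heading rate per bin, a least-squares line through
the bin medians, and finally an origin-constrained regression of the 24
slopes on $1/(d\,\alpha_{\text{rad}})$ giving $c_\omega$. Angles enter
in radians so $d\,\alpha$ is an arc length; reporting uses degrees. The
response is the *next-second* heading rate, matching the Markov
model's timing. Records whose lattice leaves the field are dropped at
annotation time; at simulation time the same event terminates the path.

## Calibration

Design rows pair the response at $t_{k+1}$ with covariates at $t_k$:
intercept, $w_c$, $w_t$, $w_o$, $h_{agl}$, the predictor at lags 5, 10,
30 s, and $\Lambda$ in the heading-rate mean model only (the error
models never see $\Lambda$; its binned scatter shows no dependence).
Rows lacking full 30-s history, rows above the rotor-swept zone, and
non-finite rows are dropped; surviving rows are pooled across tracks
with no track identity. The mean model is ordinary least squares with an
explicit rank check that names collinear columns. The error model
regresses $|\epsilon|$ on the same covariates and scales the
coefficients by $\sqrt{\pi/2}$ — the half-normal correction
$E|\epsilon| = \sigma\sqrt{2/\pi}$ — so the fitted object is literally
the linear $\sigma(\psi)$ form of the model equation; a variant
regressing $\epsilon^2$ (predicting $\sigma^2$) sits behind
`error_method="squared"`. Fitted $\sigma$ is floored at
$\sigma_{\min}$ (default 1% of the predictor's calibration standard
deviation) so simulation noise can neither vanish nor go negative. An
intercept is included in both stages: a zero-mean constraint would be
unjustified. Calibration is deterministic; the model file is JSON and
round-trips float64 bit-exactly.

## Simulation

Paths start from a Gaussian draw of the smoothed posterior at a
reference track's first second (per-component variances; zero variance
means deterministic), with lag buffers held constant at the initial
values. Each step assembles covariates at the current location, draws
the three predictors from their calibrated Gaussians, and advances by
explicit Euler with the *pre-step* heading steering the displacement and
the freshly drawn predictors applied over the step. Horizontal speed is
floored at 0.1 m/s (heading is undefined at rest), and all three
predictors are clipped to generous physical envelopes for a large raptor
(|v_z| ≤ 20 m/s, v_h ≤ 40 m/s, |ω| ≤ 60 deg/s) — a guard that keeps a
marginally unstable calibrated autoregression from diverging without
affecting ordinary flight. A path ends when its position or any
look-ahead point leaves the domain. Each path draws from its own
substream spawned from the ensemble seed, so path i is bit-reproducible
independent of ensemble size or other paths' termination. Wind is held
static over the 3-min horizon.

With the error model zeroed the integrator is exact in speed (per-step
displacement $v_h T$) and closes a constant-$\omega$ circle to machine
precision over a full turn — the discrete path is a regular polygon.

## Validation and risk maps

Validation windows are 3-min segments (181 states) drawn uniformly
without replacement from windows with at least 75% rotor-swept-zone
occupancy. For each window, 100 paths are simulated and the 3D radial
distance to the reference is pooled per time lag (truncated paths
contribute while alive); quartiles are reported in meters and rotor
diameters (D = 130 m). The comparison standard is the constant-velocity
baseline — straight-line extrapolation of the initial state. Condition
subsets stack cumulatively: windy (wind ≥ 5 m/s), + RSZ
(AGL < 200 m), + soaring (updraft ≥ 0.75 m/s); both thresholds
inclusive and configurable. Risk maps assign simulated RSZ states to
nearest grid nodes (counts conserved, asserted), smooth with the same
250-m Gaussian convention, and normalize by the maximum into [0, 1];
default reporting windows are 0–2.5 min and 2.5–3 min.

## The synthetic study

The generator replaces restricted eagle telemetry and defines the study
conditions:

* **Terrain**: a north–south Gaussian ridge (250 m high, 350 m wide)
  over a 300-m base, plus smooth relief of 60 m amplitude and 700 m
  correlation length, on a 10-m lattice over 8 × 16 km. The relief is
  not cosmetic: over a perfectly uniform ridge the steering law operates
  in closed loop — birds settle where the look-ahead covariate is zero
  and stay there — leaving almost no exogenous covariate variation, and
  $c_\omega$ becomes practically unidentifiable. Summit/saddle relief at
  roughly twice the longest look-ahead range keeps the updraft field
  locally linear across the 28-point lattice (so the per-pair slopes
  collapse cleanly) while continually displacing the lift maxima that
  generate identifying variation. This mirrors real ridgelines, which
  undulate at kilometer scales.
* **Truth model** (known weights): horizontal speed is a stable
  autoregression with stationary mean ≈ 11 m/s nudged by tailwind and
  updraft; vertical speed seeks ≈ 90 m AGL over strong lift and sinks
  elsewhere; heading rate is the pure look-ahead law
  $\omega_{k+1} = c_\omega \Lambda_k + \epsilon$ with $c_\omega = 30$
  and σ = 1.2 deg/s, *without* self-persistence or wind terms. The
  discovery procedure estimates a marginal ω–Δw₀ relation; any
  heading-rate persistence would inflate that marginal slope by the
  autoregressive steady-state gain and make "recovery of $c_\omega$"
  ill-defined. Calibration still fits the full covariate list; the
  superfluous coefficients estimate near zero on ideal data.
* **Observation process**: inter-fix intervals drawn from a discrete
  3–15 s distribution with median 6 s and ~80% of mass at or below 6 s
  (the typical bulk cadence of solar GPS units on large raptors), 2%
  above the 10-s gap rule;
  Gaussian noise of 2 m per horizontal axis and 6 m vertical.
  Calibration-grade truth tracks last 7 min so their degraded fixes can
  survive the 5-min segmentation rule (a 3-min track never can); 3-min
  validation windows are cut afterwards.
* **Starts**: rotor-swept-zone altitudes over windward slopes (top
  15% of the updraft field), cruising speeds, uniform headings.

What the synthetic study does **not** emulate: behavioral repertoires
(perching, thermalling, hunting), thermal updrafts, wind-field
variability in time or altitude, DEM error, individual (age/sex)
variation. Passing recovery tests therefore demonstrates that the
pipeline's estimators are correct and that the study design is
identifiable — not that real eagles follow this model class.

### What the observation process costs: an aliasing analysis

Three controls isolate how much of the generating model survives the
GPS observation process (all computed by the test suite and acceptance
harness):

1. **Calibration on noiseless 1-s tracks** recovers every mean weight
   and the look-ahead coefficient essentially exactly — the estimators
   are unbiased when their input is the modelled process.
2. **The full pipeline under an idealized observation process**
   (1-s sampling, negligible noise) still recovers the weights to a few
   percent — preprocessing, smoothing, annotation, and design assembly
   introduce no material bias of their own.
3. **The full pipeline under the realistic observation process**
   (median 6-s variable sampling, 2/6-m noise) degrades markedly: the
   1-Hz model is fitted to *interpolated* states, so the lag regressions
   partly measure the smoother's correlation structure rather than the
   generating dynamics — lag weights are strongly distorted, and the
   conditional look-ahead weight inflates through that distortion. The
   rediscovered $c_\omega$ (the marginal estimand) is noisy across
   terrain/track realizations: some seeds land within a few percent of
   truth, others 25–30% low.

This is temporal aliasing, not an implementation defect: per-second
innovations simply are not observable at 6-s sampling. It is also a
substantive caution for fitting 1-Hz movement models to interpolated
telemetry of real birds. The acceptance harness reports the recovery
numbers as measured.

## Known limitations

* The look-ahead law's per-pair discovery attenuates when the updraft
  field has curvature at look-ahead scales (the pairs decorrelate);
  the collapse regression then underestimates $c_\omega$.
* Negative-AGL simulation (flight "below ground") is permitted by
  design; over very steep synthetic terrain it can be more frequent
  than in real data.
* Wind is constant within a simulation and the updraft estimate scales
  linearly with wind speed at a fixed reference height; altitude decay
  and terrain-complexity corrections are out of scope.
* The error model is linear in covariates and can predict negative σ
  for extreme covariates; predictions are floored at σ_min rather than
  re-parameterized.
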