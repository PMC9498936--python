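# Methods

`divechaos` analyzes a one-dimensional depth record of a free-ranging diving
animal as the observable of a dynamical system.  This note documents the
model, the estimators, their tunable parameters, and the numerical choices
the implementation makes where the method leaves the design open.

## State-space reconstruction

A depth series x(t), sampled at interval dt (1 s throughout), is unfolded
into delay vectors

    y(i) = [x(i), x(i + tau), ..., x(i + (m-1) tau)].

For a deterministic system observed through one coordinate this
reconstruction is diffeomorphic to the underlying attractor for suitable
delay tau and embedding dimension m, so recurrent behavior (quasi-periodic
dive bouts, near-surface rest) becomes recurrent geometry: bouts trace
closed orbits away from the origin, rest collapses toward a near-origin
core, transitions connect the two along the coordinate planes.

**Delay selection.** tau is placed at the first local minimum of the
auto-mutual-information (AMI) curve, with the first zero crossing of the
autocorrelation recorded as a cross-check and used as a flagged fallback
when no interior AMI minimum exists.  Because multi-week biologging records
are non-stationary, the curves are computed on non-overlapping 6-h segments
and summarized by their pointwise median.  Numerical choices:

- AMI uses an equal-width histogram estimator with 32 bins.  Only the
  *location* of the first minimum matters; 32 bins locate it to about one
  sample on sinusoidal test signals, while coarser or finer binning shows
  sample-scale aliasing of the argmin.  The plug-in bias (about
  (B-1)^2 / 2n nats) is irrelevant to the argmin.
- Segments share one common bin range taken from the whole record.
  Per-segment ranges would let an all-rest segment re-resolve metre-scale
  respiration wiggles and inject spurious short-lag minima into the median
  curve.
- A local minimum must be the strict minimum of its +-30 s neighborhood
  (sample-scale jitter on a slowly decaying curve otherwise produces
  spurious early minima), and the reported tau is the vertex of a parabola
  fitted through twice that neighborhood — the AMI valley is locally
  quadratic and the raw argmin is limited by estimator jitter.
- The AMI maximum *beyond* the first minimum is reported as a
  dominant-cycle proxy (the curve always decays from lag 0, so the raw
  maximum over positive lags would sit at the first lag).

**Dimension.** The false-nearest-neighbor (FNN) profile uses Kennel's
distance-ratio criterion only: the nearest neighbor pair (i, j) in
dimension m (Theiler exclusion of one dominant period; exact search; ties
to the smaller time index) is false when the extra-coordinate separation
exceeds R_T = 3 times their m-dimensional distance.  Pairs identical to
machine precision (exactly recurrent orbits) are true neighbors, not
ratio-test candidates.  Records longer than 200k points are strided, and
the stride is reported.

Two estimator properties matter for interpretation and for what the tests
can show:

- On strictly periodic noise-free signals sampled over many cycles, other
  cycles supply near-exact same-phase neighbors in *any* dimension, so the
  ratio criterion only resolves the fold of a sinusoid (m = 2) when the
  record holds a few cycles and the Theiler window excludes same-phase
  recurrences.  The dimension-selection tests use that regime.
- On records whose state switching is stochastic (the simulator's
  semi-Markov transitions, and plausibly real animals), a floor of
  genuinely unpredictable neighbors remains at every m — a bottom-phase
  point cannot predict the next cycle's jittered target depth.  The
  analysis therefore embeds depth records at m = 3 by default — three
  coordinates resolve the orbit/core/transition geometry, matching the
  FNN knee of the deterministic part of the repertoire — and exposes
  FNN-based auto-selection as an option rather than the default.

## Window invariants

Features are computed in 30-min windows sliding by 10 min (a window spans
roughly two deep-dive cycles).  Each window's raw samples are embedded
with the global (tau, m); per window:

- **L** (m): Euclidean distance of each embedded point from the origin;
  summarized by median (robust to single deep spikes) and mean.
- **E_k** ((m/s)^2): v^2/2 with v the state-space speed
  ||y(i+1) - y(i)|| / dt; median and mean.  Zero would mean no vertical
  motion at all; rest sits near the observation-noise floor.
- **Lambda_m** (1/s): Rosenstein maximum Lyapunov exponent — each point is
  paired with its nearest neighbor beyond a temporal exclusion, the mean
  log pair distance is tracked over a fit horizon, and the exponent is the
  least-squares slope.  Within a 30-min window a one-dominant-period
  (17-min) exclusion would leave almost no admissible pairs, so both the
  exclusion and the fit horizon are capped at a quarter of the window.
  Long fit horizons are evaluated on a strided step grid (the curve is
  smooth; the slope is unchanged).  A window whose pairs never separate
  (exact recurrence) reports 0 with a degeneracy flag.
- **d** (dimensionless): Grassberger–Procaccia correlation dimension —
  pair counts C(r) over 24 log-spaced radii between the 1st and 50th
  percentiles of the pair distances (same Theiler exclusion), with the
  scaling region chosen automatically as the longest run of at least five
  consecutive local log-log slopes whose spread stays within 0.2; d is the
  OLS slope over that run.  The estimate is reported as measured rather
  than clipped into [0, m]: clipping would pile an artificial atom of
  probability mass at exactly m (noise-dominated windows fluctuate
  slightly above it), which downstream mixture fitting would chase.
- **dominant period** (s): argmax over periods of the time-averaged
  analytic-wavelet power.  An analytic Morlet (omega0 = 6) evaluated in
  the frequency domain with the Torrence–Compo normalization is used, in
  which white noise has flat expected power across scales; only the argmax
  is consumed, which is robust to the analytic-wavelet choice at these
  bandwidths.  Per-window periods are read from the record-level
  transform averaged within each window (no per-window edge artifacts;
  periods longer than the window stay resolvable).  Estimators that fail
  on a window contribute NaN plus a flag, never a fabricated value.

All quantities are relative measures for comparing windows, not precision
estimates of dynamical invariants.

## Behavioral-state decoding

Windows described by (L_med, Ek_med, Lambda_m, d) are clustered with
Gaussian mixtures (EM, 20 seeded k-means++ restarts, convergence at 1e-6
relative log-likelihood, max 500 iterations), with diagonal covariances
either per component or shared.  Component variances are floored at 1e-5
of each feature's overall variance, which blocks EM collapse onto a
handful of near-identical values.

**Feature scale.** The behavioral states of a diving record are separated
by *ratios* — rest sits about two decades below a deep bout in kinetic
energy and almost two in L — so the strictly positive invariants (L_med,
Ek_med) enter the mixture as logarithms by default; signed features stay
raw, and `scale="raw"` restores untransformed fitting.  On raw scales a
diagonal mixture spends components on linearly distinct but behaviorally
meaningless material (windows straddling a bout edge, whose mixed delay
coordinates land mid-way between orbits) while merging the ratio-separated
near-surface states.  k-means++ seeding measures distances in the same
transformed space.

**Choosing k.** AIC (2p - 2 loglik, with p the free-parameter count of the
structure) is scanned over k = 1..6 for both structures.  "No obvious
improvement" is operationalized scale-invariantly: components are added
while each AIC step improves by at least 8% of the total AIC drop across
the scan *and* by more than twice the added parameter count (a gain of the
order of the added parameters is indistinguishable from overfitting).  A
threshold relative to |AIC| itself would depend on measurement units,
since rescaling any feature shifts the log-likelihood by a constant per
window.  The structure with the lower AIC at its selected k wins.

**Labels.** Soft posterior responsibilities give each window a confidence;
hard labels break ties toward the lower component index.  Components are
tagged semantically by ordering their mean L (descending): deep-bout,
shallow-bout, ..., near-surface-shallow, with near-ties falling back,
flagged, to mean kinetic energy.  Budgets are reported for all assigned
windows and for the high-confidence (>0.9) subset.

## The simulator

`synthetic.simulate_dive_record` generates records from a semi-Markov
grammar over four states — rest R, shallow bouts B_s, deep bouts B_d,
intermediate near-surface activity I — with exponential-with-floor
durations, diurnally modulated transition weights, and fully explicit
seeding.  Defaults (the generator's study conditions):

- dive cycles: 1020 s (B_d) and 510 s (B_s), trapezoidal with
  cosine-smoothed corners, constant descent/ascent *time* (~35% of the
  cycle each, so shallower dives descend more slowly and every cycle has
  the same speed composition), a tapered sinusoidal bottom "foraging
  wiggle", and surface pauses; per-bout target depths are drawn from a
  clipped normal at the middle of the depth law (B_d 250-600 m,
  B_s 30-100 m) — time-at-depth in real records is unimodal — with 4%
  per-cycle jitter and optional per-cycle drift (telescopic bouts);
- near-surface states: slow mean-reverting drift plus a respiration-scale
  oscillation (R: 1-6 m level, 0.8 m / 90 s oscillation; I: 15-30 m
  level, 4 m / 120 s oscillation) — resting animals are not motionless,
  and the oscillation gives these states a coherent low-dimensional orbit;
- mean episode durations R 3 h, B_s 2 h, B_d 3.5 h, I 1.25 h with floors
  of 2-4 dive cycles; vertical speeds bounded by 2 m/s; observation noise
  0.04 m (a smoothed time-depth-recorder series);
- diurnal forcing: transition weights into R scale with
  1 + a cos(2 pi (h - 13.5)/24) (solar culmination shortly after 13:00
  local), weights into B_s with the opposite sign at half that amplitude
  (shallower diving at night), a = 0.3 by default and both amplitudes
  independently settable.

`stationary_fractions` returns the expected time budget: for each hour the
embedded-chain stationary distribution weighted by mean durations,
averaged over 24 h (quasi-static in the forcing; exact when the modulation
is off).

**What the simulator does and does not emulate.** It reproduces the depth
ranges, quasi-periodicities, bounded speeds, near-surface structure and
diurnal occupancy modulation that the analysis relies on.  It does not
model horizontal movement, energetics, prey fields, depth quantization, or
deterministic chaos: state switching and bout depths are stochastic, so a
positive Lyapunov exponent or a saturating FNN knee on simulated records
reflects that stochasticity, not chaos.  Passing tests show the pipeline
recovers known structure of this class; they cannot certify behavior on
real records, whose states are less cleanly separated.

Two statistical limits of the study conditions matter when scoring
recovery on 7-day records:

- with hours-long exponential episodes, a single week holds only ~100
  episodes, so a record's realized time budget deviates from the
  configured stationary fractions by several points (about half of seeds
  exceed 5 points somewhere even with perfect labels); recovered budgets
  are therefore scored as means across seeds, where realization noise
  averages out;
- windows straddling bout boundaries (~15-20%) carry mixed delay
  coordinates and form a genuine fifth feature-space structure whose
  AIC weight sits near the selection threshold, so the chosen component
  count can land at 3 or 5 on some seeds.

## Summaries

Hour-of-day tables bin windows by their midpoint on a configurable local
clock (offset 0 by default; the simulator already writes local time) into
bins that tile 24 h exactly; percentiles P5/P50/P75 per bin.  Day is
06:00-18:00.  The day/night eCDF comparison reports the Kolmogorov-style
maximum gap as a descriptive statistic — no hypothesis tests are attached.
Time budgets normalize over assigned windows, with a grouped deep+shallow
"bouts" row; cumulative tag counts are per window.  Before/after
comparisons report medians over symmetric spans around a split date with a
seeded 1000-resample bootstrap percentile interval.  All summaries are
pure functions of their inputs.

## Known limitations

- The ratio-only FNN criterion saturates on stochastic records (above);
  dimension auto-selection is for deterministic benchmarks and the
  deterministic part of a repertoire.
- The within-window Lyapunov exponent and correlation dimension are noisy
  at 30-min windows; they enter the mixture as weak features, and windows
  where they fail are flagged rather than filled.
- The AIC knee has no unambiguous definition; the scan table is always
  persisted so the choice can be audited.
- Hour-of-day summaries use a fixed UTC offset rather than per-day solar
  time; over multi-month records the culmination drifts by tens of
  minutes.
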