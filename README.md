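# divechaos

Chaos-theoretic analysis of marine-mammal dive records: time-delay
embedding of a 1-Hz depth series, attractor invariants in sliding windows,
unsupervised behavioral-state decoding, and diurnal time-budget summaries
— plus a synthetic dive-record simulator with known ground-truth states
that makes every stage testable.

## The problem and the approach

A multi-week depth record from a diving animal (the motivating case is a
satellite-linked time-depth recorder on a narwhal, *Monodon monoceros*) is
a continuous behavioral stream: deep foraging bouts, shallow bouts,
near-surface rest, and the transitions between them.  Threshold-based dive
segmentation discards the near-surface structure; hidden-Markov analyses
require committing to a state count up front.

`divechaos` instead treats depth x(t) as the observable of a dynamical
system and reconstructs a state space by time-delay embedding,

    y(i) = [x(i), x(i + τ), ..., x(i + (m−1) τ)],

with the delay τ chosen at the first local minimum of the auto-mutual
information I(τ) and the dimension m where the false-nearest-neighbor
fraction becomes negligible.  Recurrent behavior becomes recurrent
geometry: bouts are orbits, rest is a near-origin core.  Sliding 30-min
windows are then summarized by attractor invariants —

- L = ‖y‖, distance from the origin (m),
- E_k = v²/2, kinetic energy along the trajectory ((m/s)²),
- Λ_m, the Rosenstein maximum Lyapunov exponent (1/s),
- d, the Grassberger–Procaccia correlation dimension,
- the dominant cycle period from an analytic-wavelet scalogram (s)

— and decoded into behavioral states with a Gaussian-mixture model
(diagonal or shared-diagonal covariances, AIC-guided component count, soft
memberships).  Ordering components by L yields semantic tags (deep-bout,
shallow-bout, intermediate, near-surface), from which time budgets,
hour-of-day partitions, day/night eCDFs and before/after comparisons
follow.

## A worked example

`examples/` holds one short narrative script per capability.  From
`examples/02_select_embedding_parameters.py` (two simulated days, seed 3):

```
delay tau:        309 s  (method: ami_min)
ACF zero cross:   474 s  (cross-check)
AMI peak beyond:  1020 s  (dominant-cycle proxy)
FNN fraction by m: {1: 0.975, 2: 0.741, 3: 0.494, 4: 0.294}
sine FNN by m:    {1: 0.938, 2: 0.0, 3: 0.0}
sine dimension:   2
```

The delay lands near a quarter of the ~17-min (1020 s) deep-dive cycle,
the autocorrelation zero crossing agrees to within a couple of minutes,
and the AMI maximum beyond the minimum recovers the cycle itself.  The FNN
fraction on the simulated record drops steeply but keeps a floor — the
simulated animal switches bouts stochastically, so some neighbors stay
genuinely unpredictable at any m — while on a deterministic benchmark the
knee is clean at m = 2.  Depth records are embedded at m = 3 (see
`docs/methods.md`).

From `examples/04_decode_states.py` (three days): the AIC scan, the
semantic tags, the time budget, and a confusion table of decoded tags
against the simulator's true states.

A thin command line mirrors the library for shell use:

```
divechaos simulate --duration-days 2 --seed 3 --out rec.csv
divechaos select-params rec.csv
divechaos run config.yaml --out results/
```

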