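# Methods

## Model and assumptions

The unit model is the quadratic integrate-and-fire (QIF) neuron
`dv/dt = b + v²` with reset `v_peak → v_reset` (defaults 1 → 0). It is the
normal form of the saddle-node-on-a-limit-cycle family: for `b < 0` there
is a stable rest state at `−√(−b)` and a saddle at `+√(−b)`; the lines
`b = 0` and `v_reset = +√(−b)` are bifurcation boundaries and are reported
explicitly as *on-bifurcation* by the regime classifier rather than being
absorbed into a neighboring regime. Proximity to the codimension-2 SNHO
point `(b, v_reset) = (0, 0)` is what makes *weak* diffusive coupling
anti-phase-promoting — the mechanism behind dynamic frustration.

Coupling is purely diffusive, `g (v_j − v_i)`: gap junctions pass
sub-threshold currents, not spike pulses. When a unit resets, its
partners see the post-reset value from the crossing instant onward; no
delta-pulse is transmitted. The periodic drive is itself a QIF unit `u`
(reset 1 → 0, so its period is exactly the analytic transit time
`T = b0^(−1/2) arctan(b0^(−1/2))`) coupled one-way into every neuron with
strength `g0`; it represents bath-applied ATP and therefore also reaches
nodes whose gap junctions are disrupted.

Heterogeneity is specified on periods, not on `b`: τᵢ ~ Normal(T, T/10),
redrawn while τᵢ ≤ T/100 (a guard that essentially never fires at sd
T/10), then inverted through the period formula by bracketed Brent root
finding (round-trip accurate to better than 1e−10 relative).

## Numerical integration

Fixed-step RK4 (Euler available for convergence checks) with per-step
threshold handling: when a step carries a component across `v_peak`, the
crossing time is located by linear interpolation within the step,
recorded as the spike time, the component is set to `v_reset` at that
instant, and the step remainder is advanced with one explicit Euler
sub-step. The dynamics are bounded on `[v_reset, v_peak]`, so no blow-up
handling is needed beyond the reset. Default `dt` is the smallest
analytic period in the system divided by 1000; a configuration error is
raised above `τ_min/200`. At `dt = τ/1000` the RK4 period error is at
rounding level (~1e−12 relative); Euler shows clean first-order decay.

Initial voltages are drawn uniformly on `[v_reset, v_peak)` per unit per
trial (the model file gives no initial conditions; random phases are
required for desynchronization transients and trial averaging); the
drive starts at `u(0) = 0`.

One integration kernel serves the driven pair, lattice networks, and
batched trial ensembles (trials stacked as a block-diagonal adjacency;
the drive is a single shared component since its trajectory is
trial-independent). Reductions between these paths are therefore
bit-exact, and the test suite asserts them.

## Lattices and trials

Square lattices include each nearest-neighbor edge independently with
probability p; triangular lattices use a row-offset embedding — node
(r, c) neighbors (r, c±1), (r±1, c), (r±1, c+(−1)^r) — giving interior
degree 6, and disruption removes all edges of each node independently
with probability q while the node keeps receiving the drive. Boundaries
are non-periodic (a finite field of view): edge nodes simply have fewer
neighbors.

Per trial, the seed hierarchy `(base_seed, trial) → {lattice,
heterogeneity, initial conditions}` uses independent child streams, so
changing p alone does not reshuffle the bᵢ draws, and edge sets are
nested across p for a fixed seed (one uniform draw per candidate edge).

Lattice study conditions: 18×18 square (p ∈ {0, 0.75}) and 10×10
triangular (q ∈ {0, 0.5}), T = 20, 8 drive periods per simulation.
Cell–cell coupling for lattice runs defaults to the weak regime,
g = 1/(3T) (gT = 1/3, the weak anchor of the pair dichotomy), and drive
strength g0 = 1/T; both are exposed in configuration since the source
experiments state only "weak regime".

## Deviation score and other statistics

Within each moving window (width = stimulus period T, stride T/4 by
default) every node's segment is affinely rescaled to [0, 1]; a node's
window score is the trapezoidal integral of the absolute difference from
the population mean of the normalized segments, divided by the window
width. Per-node scores average over windows; constant (degenerate)
segments normalize to zero, are excluded from that node's average, but
still enter the population mean. Windows are free-running (not aligned
to stimulus onsets), matching the uncertainty of stimulus arrival in
recordings. Conclusions are stride-insensitive between stride = width
and width/4.

Cross-correlation is zero-lag Pearson over full records (the 0.8
threshold presumes a normalized, bounded statistic; no lag search). The
sync fraction counts pairs *strictly* above threshold. Spike-phase
offsets discard the first two thirds of the record as locking transient
and fold circular distances to [0, T/2]. Scaling exponents are
least-squares slopes of log(score) against log(T), requiring ≥ 4 grid
points.

## Synthetic data generator

The generator emulates grid-patterned calcium recordings: a square-wave
stimulus (duty 0.5, periods 40–200 s, 1 s sampling, 8 cycles), per-node
per-cycle onset delays δt ~ Poisson(α·T) in seconds (α = 0.05 s⁻¹, so
σ ≈ 3.2 s at T = 200 s, small against the 100 s ON half-cycle; delays are
clipped to the ON half and clips counted), a peak-normalized double
exponential transient (rise 2 s, decay 10 s — typical GCaMP-like
timescales), 10% per-node amplitude jitter, and additive Gaussian noise
of sd 0.005 on a fold-change baseline of 1.0 (high-SNR imaging; chosen so
that the delay mechanism, which alone yields a deviation-vs-period
exponent of −0.50, dominates the T-independent noise floor — at sd 0.01
the fitted exponent already flattens to −0.40). Delays are redrawn each
cycle: the scaling argument concerns per-stimulus activation noise, not a
fixed node property. Nodes sit at 70 µm center spacing (20 µm radius,
30 µm edge-to-edge); nearest-neighbor pairs are bridged independently
with probability p, and for p = 0 all nearest-neighbor pairs are emitted
tagged `spatial_nearest` (a deterministic superset of randomly sampled
nearest pairs — disconnected layouts are still scored on nearest nodes
in space).

What the generator does **not** emulate: gap-junction coupling between
nodes (coupled dynamics come only from the mechanistic simulator),
imaging artifacts (bleaching, drift, segmentation error), and
within-node cell-count variation. Tests passing on synthetic data
therefore validate the metrics pipeline and the delay-noise scaling
mechanism, not the fidelity of any particular recording.

Every dataset carries a JSON manifest from which it regenerates
byte-identically.

## Problem sizes

Reported quantities use: 12 spiking periods for the period check; 20
random-phase seeds over 60 drive periods for the coupling dichotomy;
100 trials per grid point for the pair sweeps; 10 trials per p (18×18)
and 8 per q (10×10) for the lattices; and 20 dataset seeds per period
(50 nodes, 8 cycles) for the synthetic scaling fit. These sizes give
standard errors well below the effect sizes they report (e.g. the
lattice connectivity effect is ≈ 0.045 against a trial-to-trial sd of
≈ 0.002) while keeping a full recomputation under a minute on one core;
the full study conditions (1000 / 30 / 15 trials) are available via the
`scale` configuration field.

## Known behaviors and limitations

- **Frustration is non-monotone in coupling.** With drive present
  (T = 20, g0 = 1/T) the mean deviation rises with g through the weak
  regime, peaks near the weak/strong boundary g ≈ 1/τ, and falls again
  for strong coupling, where mutual in-phase locking wins — consistent
  with the undriven pair dichotomy (weak anti-phase / strong in-phase).
  This was cross-checked against an independent adaptive event-based
  integrator (`scipy.integrate.solve_ivp` with terminal reset events).
- **The period-sweep decay is steeper than T^(−1/2)** under these
  conditions: with g0 fixed at 0.1 the effective entrainment strength
  g0·T grows with T, and locking becomes near-perfect by T = 100
  (mean deviation ≈ 0.0025), giving a log-log slope ≈ −1.2 over
  T ∈ {5…100} (insensitive to 4/8/16-period durations). The
  noise-driven T^(−1/2) law is recovered exactly by the synthetic
  delay-noise pipeline, where it is the designed mechanism.
- The deviation score of two nodes offset by half a period approaches
  its anti-phase bound 0.5 only in the boxcar-kernel limit; exponential
  transients keep it strictly below.
- No synaptic (pulse) coupling, no conductance-based models, no
  periodic boundaries, no lag-resolved correlograms or spectral
  coherence in this version.
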