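# Methods

This note records the modelling conventions, default parameters, and
numerical choices the package commits to, with the reasoning behind each.

## Neuron models and discretization

All dynamics are discrete-time with step Δt = 14 ms by default. Decay
strengths are derived from time constants as `d = exp(−Δt/τ)`, with two
sentinels: τ = 0 maps to d = 0 (no memory) and τ = ∞ to d = 1 (perfect
integration). The three models form a nested family:

| model | synaptic decay α | membrane decay β | mults/neuron/step |
|---|---|---|---|
| IF | 0 (structural) | 1 (structural) | 0 |
| LIF | 0 (structural) | exp(−Δt/τ_mem) | 1 |
| CUBA-LIF | exp(−Δt/τ_syn) | exp(−Δt/τ_mem) | 2 |

Update order per step: the synaptic current folds in decayed history plus
weighted presynaptic spikes from the *previous* step (one-step
input/readout latency), the membrane adds the decayed potential and the
current, a **hard reset** zeroes the membrane if the neuron spiked on the
previous step, and the spike condition is `U ≥ ϑ` with ϑ = 1, i.e.
Θ(0) = 1 — equality fires. The reset multiply is treated as a gating
select, not arithmetic, so it does not appear in the operation budget;
each neuron's single threshold test contributes one comparison per step.

The readout layer is non-spiking (no threshold, no reset) and shares the
hidden layer's model kind and decay values. Class prediction takes the
per-class **maximum membrane potential over time**, with ties resolved
to the lowest class index.

## Training

Backpropagation through time is implemented by hand in numpy (reverse
adjoint recursion over the unrolled graph). Choices:

- **Surrogate derivative**: fast sigmoid, `dS/dU ≈ 1/(1 + β̃|U−ϑ|)²`
  with steepness β̃ = 100.
- **Reset gradient**: by default the reset gate `(1 − S[t−1])` is held
  constant in the backward pass (no gradient flows through the reset
  path). `grad_through_reset=True` enables the full path; both modes are
  validated against the scalar oracle.
- **Loss**: softmax cross-entropy on the per-class max-over-time readout
  potentials; the gradient is routed to the arg-max time step (first one
  on ties); batch losses are averaged.
- **Optimizer**: Adamax with β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
  bias-corrected first moment, infinity-norm second moment.
- **Initialization**: Gaussian weights with std 1/√fan-in.
- **Heterogeneous decays**: trainable per-neuron decays are parameterized
  as `sigmoid(raw)` so they stay in (0, 1). Structural zeros/ones (α for
  IF/LIF, β for IF) are never trained. The random-initialization mode
  draws decays uniformly from (0.05, 0.995) — wide enough to span
  sub-step to multi-second effective time constants while keeping
  `−Δt/ln(d)` finite. Readout decays are fixed (never trained), so the
  readout remains a passive integrator of the hidden code.

## Synthetic generators

Both generators emit event streams (times in seconds, channel indices)
over a 20-channel, 700 ms window (50 steps of 14 ms) with 4 classes by
default; they emulate the *information structure* of event-camera/audio
benchmarks, not their physics (no sensor noise model, no refractoriness,
no channel crosstalk).

- **Temporal** task: channels are split into G = 4 groups; each class is
  a distinct permutation of the group activation order. Each group emits
  `burst_size = 15` events at its slot center, jittered by σ = 7 ms
  (clipped to the window) on a random channel within the group. Because
  every class activates every group exactly once, spike *counts* are
  rate-matched across classes by construction — only timing carries
  label information. A count-based linear classifier stays at chance
  (verified in the tests).
- **Spatial** task: each class elevates a disjoint block of channels to
  `rate_contrast = 3×` the base Poisson rate; event times are uniform,
  so only *which* channels fire carries information. `base_rate_hz = 5`
  keeps bin occupancy near 10 %, below the saturation regime in which
  binary binning would erase the rate contrast (at 10 Hz, ~20 %
  occupancy, leak-free networks start failing for reasons unrelated to
  the code structure — this calibration was fixed before any acceptance
  thresholds were written).
- `shuffle_times` redraws event times uniformly while conserving
  channels and counts — the control that destroys timing information.

Binning uses half-open bins `[k·Δt, (k+1)·Δt)` with binary clipping
(multiple events in a bin count once) and drops events at or beyond the
horizon.

## Desk-scale directional study

`benchmark.directional_study` freezes a protocol small enough to run in
under a minute yet large enough to separate the models: 128 hidden
units, batch 16, learning rate 5e−3, 30 epochs, 3 weight seeds per
condition, LIF τ_mem = 70 ms. The τ_mem choice is deliberate: at 0.1×
the stimulus window, a feedforward LIF demonstrably cannot bridge the
inter-slot gaps of the temporal task, while the recurrent LIF can —
which is exactly the effect under study. (At τ_mem comparable to the
window, all models sit at ceiling on this task size and the comparison
is uninformative.) IF controls use the same protocol. All protocol
constants were fixed from calibration runs on independent dataset seeds
before the directional assertions were written, and were not adjusted
afterwards.

## Numerical and engineering choices

- Everything is float64 numpy; no deep-learning framework is used. The
  hand-written BPTT is validated to ~1e−6 (dominated by ordering of
  float operations, typically ~1e−12 relative) against a fully scalar,
  independently coded chain-rule oracle, across all three models, both
  topologies, and both reset-gradient modes.
- A naive per-neuron scalar interpreter (`reference.scalar_run`)
  reproduces the vectorized simulator exactly (1e−10) and, in
  instrumented mode, counts actual multiply/add/compare events so the
  analytic operation budget is verified against executed arithmetic
  rather than assumed.
- Self-connections in the recurrent matrix are allowed by default;
  `zero_self_connections=True` masks the diagonal at use time (the
  stored matrix is untouched so the flag is reversible).
- All randomness flows from explicit integer seeds (< 2³¹) through
  `numpy.random.default_rng`; CLI runs derive per-component seeds from a
  single master seed via CRC32-tagged `SeedSequence`, so artifacts are
  bit-reproducible across processes.
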