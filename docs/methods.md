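# Methods

`chopnet` simulates the oscillator interpretation of cochlear-nucleus
chopper neurons: mutually excitatory fast choppers (T-stellate cells) form a
pacemaker whose population clock equals the smallest chopper–chopper
synaptic delay, 0.4 ms; slower choppers with longer refractory periods skip
clock ticks and emit interspike intervals (ISIs) at integer multiples of
0.4 ms; a coincidence network reads periodicity (pitch) out of
amplitude-modulated (AM) signals; and a two-scale oscillation hierarchy
decodes ramping activity into an integration period. This note records the
model equations, the calibration of every constant the source literature
leaves open, the numerical choices, and what the synthetic protocols do and
do not establish.

## Neuron model

Chopper neurons are leaky integrate-and-fire (LIF) units advanced by
forward Euler at `dt = 0.025 ms`:

    dV/dt = (E_leak − V)/τ_m + I(t),        spike when V ≥ θ_eff(t),

with reset to `V_reset` on spiking and

    θ_eff(t) = θ + A_rel · exp(−(t − t_last)/τ_rel).

During the absolute refractory period the membrane is clamped at reset and
synaptic input is discarded; afterwards the decaying threshold increment
realizes relative refractoriness. Spike times are recorded at the step in
which the threshold is crossed (no sub-step interpolation; `dt` is far below
every interval of interest). Potentials are dimensionless: `E_leak = V_reset
= 0`, `θ = 1`. Fast choppers use `τ_m = 0.8 ms`, absolute refractoriness
0.1 ms, `A_rel = 0.15`, `τ_rel = 0.25 ms`; slow choppers use `τ_m = 2 ms`
and carry the bank's refractory period as a parameter.

The clamp-and-discard refractory convention is load-bearing: the
interval-reduction law `ISI = ceil(r/0.4)·0.4` requires that a
suprathreshold input arriving inside the refractory period is lost, not
accumulated — otherwise the slow chopper would fire at refractory end
instead of at the next clock tick.

The onset (trigger) neuron defaults to a single-spike generator: one spike
per trial at the time the drive first reaches 50% of its peak, plus a
0.7 ms latency standing in for the peripheral conduction chain. These two
conventions place the first chopper spike near 2 ms after stimulus onset, a
realistic first-spike latency; making the trigger faster than the
auditory-nerve depolarization it is supposed to ride on prevents chopping
from initiating. An optional conductance-based mode implements the
classic phasic ventral-cochlear-nucleus formulation (Na, low-threshold K,
and leak currents; 1000/200/2 nS, C = 12 pF) integrated at a 5 µs internal
step; its low-threshold potassium current limits the response to a
sustained step to 1–2 onset spikes.

## Synapse model

Each presynaptic spike releases a fixed quantum of transmitter after a
delay drawn from a normal distribution truncated to `[dt, 2·mean − dt]`
(see *Numerical choices*). Transmitter concentration decays as a leaky
integrator, `dc/dt = −c/τ_dec`, and conductance saturates as
`I = w · tanh(c/c_sat)` (graded mode). Chopper–chopper and onset–chopper
synapses instead use an impulse mode: the quantal current is briefer than
one integration step, so its entire effect is a charge
`Q = w · tanh(q/c_sat) · t_pulse` (with `t_pulse = 0.12 ms` the fixed
quantal pulse area) injected at the arrival step. This makes the
postsynaptic crossing coincide with the delivery step, so the pacemaker
clock equals the synaptic delay *exactly* and halving `dt` leaves every
spike time unchanged — a finite EPSC rise would both shift the clock off
0.4 ms and accumulate lag under step refinement. The tanh saturation and
weight linearity contracts hold in both modes. Network synapses release
deterministically; all release stochasticity lives in the auditory-nerve
module.

## Calibration of the weight scale

The source literature states constraints rather than values: the summed
auditory-nerve (AN) weight is one eighth of the chopper-synapse weight; AN
input alone depolarizes but cannot reach threshold ("enables chopping but
does not initiate it"); one chopper EPSP on top of that depolarization is
suprathreshold; one chopper EPSP from rest is not. With `θ = 1` the
defaults satisfy all four simultaneously:

| quantity | value | consequence |
|---|---|---|
| chopper weight `w_cc` | 8.3 | EPSP charge `Q ≈ 0.96 θ` (subthreshold from rest) |
| summed AN weight | `w_cc/8 ≈ 1.04` | steady AN depolarization `≈ 0.83 θ` |
| pacemaker→slow weight | 12 | charge `≈ 1.39 θ` (suprathreshold alone) |

At the 0.8 ms per-neuron cycle a fast chopper recovers to `≈ 0.5 θ` between
spikes, so delivery + recovery clears threshold with ~0.4 θ margin while
both single-cause routes stay below it.

## Auditory-nerve fan-in

The cochlea / hair-cell / vesicle chain is replaced by a phenomenological
point process per fiber (5 fibers per chopper): instantaneous rate =
half-wave-rectified waveform (phase locking) × an adaptation factor
`a_∞ + (1 − a_∞)·e^(−t/τ_a)` (`a_∞ = 0.55`, `τ_a = 10 ms`, single
exponential; depletion is described only qualitatively in the source),
thinned by a 1 ms absolute dead time. The peak instantaneous rate (3000/s)
is a convention chosen so that sustained driven rates land at 300–500
spikes/s, the physiological range for high-spontaneous-rate fibers;
stimulus level maps onto a scalar gain of this rate. Fiber spikes reach the
choppers through graded synapses (`τ_dec = 3 ms`) whose summed weight obeys
the 1/8 rule, producing a fluctuating enabling depolarization around
0.8 θ.

## Circuits and protocols

* **Pacemaker** (`build_pacemaker`): a ring of 2 (or 3) fast choppers with
  0.4 ms mutual delays plus one onset neuron wired to exactly one chopper.
  Driven by a step (current mode) or a tone burst through the AN model.
  Jitter 0: population inter-event interval exactly 0.4 ms; per-neuron ISI
  exactly `n_fast × 0.4 ms`.
* **Interval bank** (`build_interval_bank`): one slow chopper per
  refractory value, each receiving the full pacemaker output at
  suprathreshold weight. Slow choppers do not receive direct AN input by
  default (the pacemaker projection substitutes; a flag wires it through).
  Jitter 0: `ISI = ceil(r/0.4)·0.4` (+0.4 when `r` is an exact multiple,
  because blocking is strict).
* **Regularity protocol**: 500 trials of a 25 ms tone burst (1.6 ms linear
  ramps) at the unit CF 2.89 kHz, delay jitter SD 0.26 ms on the
  chopper–chopper interconnections only (the trigger synapse stays
  deterministic — jittering it smears the trial alignment the protocol's
  PSTH depends on). Analyses: PSTH at 0.3 ms bins; ISI mean/SD/CV per time
  bin with ISIs assigned by the onset spike of each pair (population SD);
  bins under a minimum count are flagged undefined, never zero-filled.

## What the jittered protocol shows — and does not

Per-delivery jitter makes the ring's event times a random walk: the k-th
PSTH peak has spread `≈ 0.27·√k ms`, so two sharp chopping peaks and a
third ~20% ripple survive at 0.8 ms spacing — peak detection therefore uses
a Poisson-noise-aware prominence floor. The per-neuron ISI distribution
stays centered on the lattice (mode 0.85 at 0.1 ms bins, CV 0.33), and the
unit classifies as a sustained chopper by the CV *level* (median CV over
defined bins after the 5 ms onset transient, threshold 0.35 — a literature
convention; a per-bin "every bin < 0.35" reading fails by sampling noise
alone at these counts). Slow-chopper ISIs under jitter are first-passage
times over the jittered event stream and concentrate just above the
refractory period rather than on the lattice: the multiples law is a
property of the deterministic clock, which is how it is asserted.

Passing these protocols shows that the modeled mechanism produces the
claimed interval structure under its own stated conditions; it does not
show that real chopper regularity arises this way, and the AN stand-in
deliberately omits cochlear filtering, level-dependent tuning and
spontaneous-rate diversity.

## Periodicity network

The coincidence layer runs on idealized event times. Per modulation cycle
the trigger fires at the envelope peak; each trigger starts an oscillator
burst (spikes at `k·τ_k`, `k ≤ 2` — the intrinsic oscillation dies after a
few cycles, which also enforces the "small integers" constraint) and one
integrator event at `n·τ_c`. A coincidence is an integrator event within
half a coincidence window (default `0.1·τ_c`) of an oscillator spike;
events are attributed to the smallest trigger separation `m` that explains
them, and the inhibitor vetoes everything but `m = 1` (the fundamental).
Solutions of `m·τ_m = n·τ_c − k·τ_k` are enumerated exhaustively over
`m, n ≤ max_int`, `k ≤ max_int` (default 10, tolerance 0.05 ms).

For the response-matrix experiment the 16 CFs are log-spaced at five per
octave over 1–8 kHz (a convention; the source figure does not print them)
and the modulation grid is `CF/6`, so each unit's BMF and second harmonic
lie exactly on the grid: with inhibition every row peaks at `CF/6`, without
it harmonic sidebands appear — the qualitative structure of the reference
figure. Units are constructed with `n = 8, k = 2`, hence `τ_k = τ_c` at
ratio 6:1.

## Ramp decoder

Fast cycles `q = 0 … n_nested−1` (complete cycles only) nest at the start
of each slow cycle; excitation windows of width 3 ms (the excitatory
fraction of a gamma cycle) are centered on the lattice points
`p·τ_slow + q·τ_fast`. A ramp crossing threshold at `t*` coincides with the
earliest window center `≥ t* − window/2`; `(p, q)` are recovered from that
center, making `decode ∘ integration_period` the identity on lattice
points. Coincidence times are monotone: non-decreasing in threshold,
non-increasing in slope.

## Numerical choices

* `dt = 0.025 ms` throughout the network engine; halving it changes no
  pacemaker spike time (impulse synapses) and all spike times are grid
  times.
* Delay jitter is truncated to the *mean-symmetric* window
  `[dt, 2·mean − dt]` by resampling. The floor preserves causality; the
  matching cap keeps the realized mean delay equal to the nominal delay. A
  one-sided floor would bias 0.40 → 0.44 ms and drag the whole interval
  lattice with it. For delay means well above the floor (e.g. 2 ms) the
  truncation is negligible and the realized SD equals the nominal SD.
* Simultaneous deliveries within one step are summed before the neuron
  update. Per-trial and per-synapse random streams are spawned
  deterministically from one master seed (`numpy` `SeedSequence`), so
  results are bit-identical across runs and independent of trial execution
  order.
* `base_interval` grid-searches bases in `(0.1, 0.45)` ms at 0.01 ms steps,
  scoring RMS deviation of the ISIs from nearest positive integer
  multiples; among equal-RMS candidates the largest base wins (otherwise
  every divisor would tie) and the grid's lower bound excludes degenerate
  tiny bases.
* Spike times serialize at fixed 6-decimal ms precision — below `dt`, so
  round-trips are exact.

## Known limitations

* The engine is clock-driven and single-threaded; it is sized for
  microcircuits (units, not populations).
* D-stellate (inhibitory) input is supported as negative-weight synapses
  but no preset wires it; in the modeled protocols the drive offset alone
  stops the self-excitation, which the `stop_condition` check verifies.
* The periodicity layer idealizes the trigger as an envelope-peak detector
  and the inhibitor as a veto rather than a spiking pathway; both are
  functional reductions, adequate for the response-matrix structure but not
  for latency or level effects.
* Under delay jitter the slow-chopper lattice dissolves (see above); only
  the deterministic protocols exhibit the exact multiples law.
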