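# Methods

## The simulated machine

`spikecore` models one digital neuromorphic core at the level of its
stored state: integer weight codes in a banked memory, per-axon scale
codes, 4-bit timers, membrane potentials, and refractory counters. One
call to `Core.step` performs a full inference-plus-learning iteration,
representing 1 ms of simulated time, in a fixed phase order:

1. load axon spikes (external OR recurrent from the previous step) and
   zero the spiking axons' timers;
2. event-driven integration: each spiking axon adds
   `scale x code x LSB` to the `N_f` neurons starting at its offset;
   refractory neurons receive nothing;
3. leak `V <- V - alpha (V - V_rest)` on non-refractory neurons;
4. fire at `V >= theta` (inclusive), reset to `V_rest`, zero the
   neuron's timer, start the refractory counter;
5. route: neuron `i < O_n` firing drives axon `N_a - O_n + i` next
   step;
6. STDP on the timer-0 sets;
7. increment all timers, saturating at 15.

Potentials are real-valued doubles; weights and scales are exact
integers, so every result is bit-reproducible given the seeds.

## Membrane model choices

The hardware description says only that a neuron in refractory "no
longer integrates synaptic input". We also freeze leak during
refractory — a reset-and-hold semantics that makes a refractory neuron
completely inert and keeps the dense reference oracle trivial to state.
`CoreConfig.leak_during_refractory` toggles the alternative (leak
continues while input is blocked). Thresholds are per-neuron, the
comparison is `>=`, and a spiking neuron cannot spike again for
`refractory_steps` whole steps.

The integration-only form of the update used with offsets is read as
showing only the synaptic term; the leak term applies every step in all
configurations, matching the full update equation.

## Banked transposable memory

Cell `(x, y)` of the logical `R x C` array lives in bank `(x + y) mod B`
at address `floor((Cx + y)/B)`; the per-window address and rotation
formulas are implemented with integer floor division exactly. Windows
must be aligned (row windows: start column a multiple of `B`; column
windows: start row a multiple of `B`) and `B` must divide both `R` and
`C`. Partial or straddling windows are rejected rather than masked —
the composer pads dimensions with zero rows/columns instead — because
the address formula is only exact for windows that do not cross a row
boundary, and rejecting keeps the contract testable. The bank word is a
single signed weight code of 1–8 configurable bits.

## Weight scaling and quantization

Per-axon raw scales are the RMS (default) or mean absolute value of the
axon's weight row. Scale codes are unsigned integers `1..2^b_pre`,
uniformly spaced, with the step chosen so the largest row statistic
maps to the top code; zero is excluded because a zero scale silences an
axon and makes the STDP code update (division by the scale) singular.
An alternative — a globally fixed scale step not normalized to the
matrix — would preserve absolute calibration across matrices at the
cost of wasting codes; normalization to the max row statistic uses the
full code range and is the default. The max/min code ratio `2^b_pre` is
exactly the factor by which the minimum effective weight change
shrinks.

`quantize_linear` clips to `[w_min, w_max]` and rounds to `2^b` evenly
spaced levels (step `(w_max - w_min)/(2^b - 1)`), stored as signed
codes. Rounding ties go to the level nearer zero so the quantizer
commutes with sign flips of symmetric data. The range search
(`grid_search_range`) scores candidates by negative reconstruction MSE
by default; a task-level evaluator can be plugged in. Inside the core
itself the convention is simpler — weight value = code x LSB — which is
what the STDP code update assumes; `ScaledWeightSet` is the analysis
container for quantization studies.

Scale factors are never updated by on-core learning; recomputing them
is an explicit user call (`compute_scale_factors`), mirroring an
off-chip update path.

## STDP

Each axon selects one of up to eight 16-entry signed kernels. Both the
causal branch (neuron fires now, axon timer indexes the kernel) and the
acausal branch (axon spikes now, neuron timer indexes the kernel) read
the same per-axon table; an asymmetric potentiation/depression profile
therefore lives in the signed values, and rules that need genuinely
different causal and acausal tables for the same axon are a known
limitation. Coincident spikes (both timers zero) are applied exactly
once, through the causal branch with `kernel[0]`. Timer value 15
participates through `kernel[15]`; since saturation maps every spike
older than 15 steps (and units that never spiked) to that tap, setting
`kernel[15] = 0` is the conventional way to expire stale pairs. Because
a timer only remembers the most recent spike, the rule is nearest-spike
STDP, and the test oracle mirrors exactly that with last-spike-time
arrays.

The stored-code change is `kernel / scale / LSB` computed in real
arithmetic, then either rounded (deterministic mode, ties half-to-even
via `numpy.round`) or applied as a single-LSB move with probability
`min(1, |change|)` (stochastic mode). Dividing before the
probabilistic draw keeps the stochastic mode unbiased for sub-LSB
changes; changes above one LSB saturate at probability 1 and move one
LSB, a deliberate hardware-like truncation. Codes clip to the signed
`weight_bits` range. Learning is gated per axon (`learn_enabled`), which
is how "apply STDP to layer 2 only" is expressed after composition.

## Composition

`compose_feedforward` derives core dimensions from the layer stack:
fan-out = widest layer padded to a multiple of `P`, neurons = all layer
blocks (routed layers first) padded likewise, axons = external inputs
plus one recurrent axon per routed neuron. Wasted pad cells are
reported. Lateral inhibition wires each routed neuron's recurrent axon
back at its own layer with negative off-diagonal codes and a zero
self-connection (a neuron must not inhibit itself). Because one neuron
has exactly one recurrent axon, a hidden layer cannot simultaneously
feed the next layer and inhibit its own — the composer rejects that
case; on hardware it needs the splitter/neuron-copy pattern. Fan-out
beyond `N_f` uses explicit axon duplication (`split_axon`): `m`
physical axons with offsets `O, O + N_f, ...` sharing one input.

## Cycle model

Per step: axon scan `ceil(N_a/P)` (the event-driven encoder checks `P`
axon flags per cycle), integration `ceil(N_f/P)` per spiking axon, fire
`ceil(N_n/P)`. Learning: each acausal event reads/writes its row
(`ceil(N_f/P)`); each causal event updates a column of `r` incident
rows — `ceil(r/P)` accesses with transposable addressing, `ceil(r/P) x P`
row reads without. Events are counted from the same timer-0 sets the
learner uses, so model and function cannot disagree. The model is
idealized (no pipeline stalls or port contention beyond
one-access-per-bank), so only orderings and scalings are meaningful:
integrate cycles exactly linear in spiking-axon count, transposable
learning never more expensive than row-only. Absolute cycle counts and
measured-hardware speedup ratios are outside what it claims.
`sops` counts only synapses actually read for integration;
`effective_throughput` is `sops x clock / total cycles`.

## Synthetic inputs

The generators emulate the study conditions, not real sensor data:

* `poisson_spikes` draws independent Bernoulli spikes per axon per 1 ms
  step with `p = min(1, rate x dt)` — rates are Hz-interpretable. A
  true Poisson count process is not used because the core accepts at
  most one spike per axon per step.
* `structured_weights` multiplies i.i.d. normal rows by log-spaced
  per-row factors over `e^(+-spread/2)`, reproducing the signature of
  trained matrices where pre-groups (rows) disperse much more than
  post-groups (columns). At spread 5 the pre-group sigma of mean |w|
  exceeds 3x the post-group sigma by construction.
* `random_core` builds seeded toy cores (default 16 axons/neurons,
  fan-out 8, alpha 0.25, theta 0.5, 2-step refractory) sized so Poisson
  input at ~100 Hz produces activity on both sides of threshold.

Passing oracle tests on these inputs shows the mechanisms are
implemented exactly as specified; it says nothing about task accuracy
on real datasets (no image data, encoders, or classifier readouts are
included).

## Test problem sizes

Oracle-equivalence tests run on toy cores (16–48 units, 120–250 steps),
the banked-memory sweep up to 256 x 256 with 128 banks and >1000 random
window operations, and stochastic-update checks at 10,000 draws; these
sizes give exact (bit-level) comparisons everywhere and binomial 3-sigma
resolution for the stochastic mode while keeping the whole suite under
a minute.

## Known limitations

* One shared 16-entry kernel per axon for both STDP branches (above).
* Membrane potentials are doubles; the fixed-point potential width of a
  real chip is not modeled.
* No multi-core composition, routing fabric, power or area modeling.
* The cycle model's absolute counts are not calibrated to hardware.
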