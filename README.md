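# spikecore

A bit-accurate software simulator of a reconfigurable digital
spiking-neural-network core, for people studying neuromorphic
architectures: how much synapse memory a network needs, how on-chip
STDP learning interacts with low-precision weights, and how a
parallelized, event-driven datapath spends its cycles.

The simulated core holds an `R x C` array of signed integer weight
codes (rows = axons, columns = fan-out slots) and `N_n` leaky
integrate-and-fire neurons updated in discrete 1 ms steps:

```
V_j(t) = V_j(t-1) - alpha (V_j(t-1) - V_rest) + sum_i s_{t,i} w_i^pre w_{i,j-O_a(i)}
```

A neuron fires when `V_j >= theta_j`, resets to `V_rest` and is
refractory for `R_p` steps. Four mechanisms around this update are the
point of the package:

* **Presynaptic weight scaling** — each axon carries an unsigned scale
  code `w_i^pre` (1..2^b_pre); effective weights are
  `scale x stored code x LSB`, so b-bit stored weights plus a few bits
  per axon replace (b+k)-bit weights. Memory cost is
  `#synapses*b + #axons*b_pre`; with 4-bit scales the minimum effective
  weight change shrinks up to 16x, which stabilizes low-precision STDP.
* **Transposable banked addressing** — the weight array is skewed
  across `B` banks (cell `(x, y)` lives in bank `(x+y) mod B` at
  address `floor((Cx+y)/B)`), so any aligned row *or* column window of
  `B` cells is one parallel access plus a barrel rotation. Learning
  (which writes columns) then runs at inference speed on standard
  single-port memory.
* **Axonal/neuronal offsets** — per-axon offsets `O_a(i)` aim each
  axon's `N_f` synapses at any neuron window, and the first `O_n`
  neurons feed back to the last `O_n` axons one step later; multi-layer,
  recurrent and laterally-inhibited (winner-take-all) topologies all
  compile onto one small weight array.
* **LUT-kernel STDP with saturating timers** — 4-bit timers count steps
  since each unit's last spike; when a unit spikes, the partner's timer
  indexes a 16-entry signed kernel table to give the weight change
  (deterministically rounded, or applied stochastically with the
  sub-LSB change as a probability).

An idealized cycle model counts how a parallelization factor `P`
(= bank count) spends cycles on scanning, integration, firing and
learning, and converts synaptic operations to throughput.

## Worked example

A 16-12-4 feedforward stack compiled onto one core, driven by 80 Hz
Poisson input for 300 steps:

```python
import numpy as np
from spikecore import (LayerSpec, compose_feedforward, count_cycles,
                       effective_throughput, memory_bits, min_step_ratio,
                       poisson_spikes, PoissonSpec)

rng = np.random.default_rng(0)
W1 = rng.integers(-3, 4, size=(16, 12)).astype(float)
W2 = rng.integers(-3, 4, size=(12, 4)).astype(float)
net = compose_feedforward(
    [LayerSpec(16, 12, W1), LayerSpec(12, 4, W2)],
    p=4, weight_step=1.0, theta=3.0, alpha=0.25, refractory_steps=1,
)
raster = poisson_spikes(PoissonSpec(np.full(16, 80.0), 300, seed=1))
hidden, out = net.run(raster)
print("input spikes :", int(raster.sum()))
print("hidden spikes:", int(hidden.sum()))
print("output spikes:", int(out.sum()))

rep = count_cycles(net.core.trace, net.core.config, transposable=True)
print("cycles (scan/integrate/fire/learn):",
      rep.cycles_scan, rep.cycles_integrate, rep.cycles_fire, rep.cycles_learn)
print("synaptic ops :", rep.sops)
print(f"throughput   : {effective_throughput(rep, 100e6)/1e6:.1f} MSOPS at 100 MHz")

print("bits 2b+4b-pre:", memory_bits(784 + 240, 784*240 + 240*10, 2, 4))
print("bits 3b plain :", memory_bits(784 + 240, 784*240 + 240*10, 3, 0))
print("min-step ratio, 4-bit scales:", min_step_ratio(4))
```

prints

```
input spikes : 387
hidden spikes: 295
output spikes: 48
cycles (scan/integrate/fire/learn): 2100 2037 1800 0
synaptic ops : 8148
throughput   : 137.2 MSOPS at 100 MHz
bits 2b+4b-pre: 385216
bits 3b plain : 571680
min-step ratio, 4-bit scales: 16
```

Each spiking axon (387 external plus the hidden-layer spikes routed
back as axon spikes one step later) costs one fan-out-window read —
3 cycles at `P = 4` for a padded fan-out of 12 — giving the 2037
integrate cycles; scan and fire costs are fixed per step. The
memory-bit lines show the accounting for a 784-240-10 network: 2-bit
weights with 4-bit per-axon scales use 385,216 bits where plain 3-bit
weights use 571,680 — a 33% reduction — and 4-bit scales make the
smallest effective weight change 16x finer.

There is also a thin CLI (`spikecore run|quantize|membits|cycles`) over
the same library; `spikecore run --config run.yaml` simulates a core
described in YAML and writes spike events, a weight dump and a per-step
trace as delimited text.

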