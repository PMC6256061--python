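"""Independent reference implementations used as test oracles.

These deliberately avoid the package's banked-memory and timer
machinery: weights live in one dense axon x neuron matrix, and STDP is
computed from explicit last-spike-time arrays (nearest-spike pairs with
saturated timing differences), so agreement with the simulator is a
genuine cross-check rather than a restatement.
"""

from __future__ import annotations

import numpy as np

TIMER_MAX = 15


class DenseCoreOracle:
    """Plain dense-matrix re-implementation of one core's semantics.

    Mirrors the contract: integrate (event-driven, refractory neurons
    blocked), leak (frozen during refractory), fire at V >= theta with
    reset and refractory, neuron i < O_n routed to axon N_a - O_n + i
    one step later, nearest-spike LUT STDP, saturating timing.
    """

    def __init__(
        self,
        n_axons,
        n_neurons,
        n_fanout,
        weight_codes,  # (n_axons, n_fanout) ints
        weight_step,
        scale_values,  # (n_axons,) reals
        offsets,  # (n_axons,) ints
        theta,
        alpha=0.0,
        v_rest=0.0,
        refractory_steps=0,
        neuronal_offset=0,
        kernel=None,  # (16,) effective-weight LUT shared by all axons
        learn_enabled=None,
        code_bits=5,
    ):
        self.n_axons, self.n_neurons, self.n_fanout = n_axons, n_neurons, n_fanout
        self.codes = np.array(weight_codes, dtype=np.int64)
        self.weight_step = weight_step
        self.scale_values = np.asarray(scale_values, dtype=float)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.theta = np.broadcast_to(np.asarray(theta, dtype=float), (n_neurons,))
        self.alpha, self.v_rest = alpha, v_rest
        self.refractory_steps = refractory_steps
        self.o_n = neuronal_offset
        self.kernel = None if kernel is None else np.asarray(kernel, dtype=float)
        self.learn_enabled = (
            np.zeros(n_axons, dtype=bool)
            if learn_enabled is None
            else np.broadcast_to(np.asarray(learn_enabled, dtype=bool), (n_axons,))
        )
        self.code_min = -(1 << (code_bits - 1))
        self.code_max = (1 << (code_bits - 1)) - 1

        self.V = np.full(n_neurons, v_rest, dtype=float)
        self.refr = np.zeros(n_neurons, dtype=np.int64)
        self.last_pre = np.full(n_axons, -(10**9), dtype=np.int64)
        self.last_post = np.full(n_neurons, -(10**9), dtype=np.int64)
        self.pending = np.zeros(n_axons, dtype=bool)
        self.t = 0

    def _dt_pre(self, i):
        return min(TIMER_MAX, self.t - self.last_pre[i])

    def _dt_post(self, j):
        return min(TIMER_MAX, self.t - self.last_post[j])

    def step(self, external):
        spikes = np.asarray(external, dtype=bool) | self.pending
        self.last_pre[spikes] = self.t

        not_refr = self.refr == 0
        # integrate, one synapse at a time
        for i in np.flatnonzero(spikes):
            for c in range(self.n_fanout):
                j = self.offsets[i] + c
                if not_refr[j]:
                    self.V[j] += self.scale_values[i] * self.codes[i, c] * self.weight_step
        # leak (frozen in refractory)
        for j in range(self.n_neurons):
            if not_refr[j]:
                self.V[j] -= self.alpha * (self.V[j] - self.v_rest)
        # fire
        fired = not_refr & (self.V >= self.theta)
        self.V[fired] = self.v_rest
        self.last_post[fired] = self.t
        # route
        self.pending = np.zeros(self.n_axons, dtype=bool)
        for i in range(self.o_n):
            if fired[i]:
                self.pending[self.n_axons - self.o_n + i] = True
        # learn: scan all pairs through last-spike times
        if self.kernel is not None and self.learn_enabled.any():
            for j in np.flatnonzero(fired):  # causal (owns coincidences)
                for i in range(self.n_axons):
                    c = j - self.offsets[i]
                    if self.learn_enabled[i] and 0 <= c < self.n_fanout:
                        self._bump(i, c, self.kernel[self._dt_pre(i)])
            for i in np.flatnonzero(spikes):  # acausal
                if not self.learn_enabled[i]:
                    continue
                for c in range(self.n_fanout):
                    j = self.offsets[i] + c
                    if not fired[j]:
                        self._bump(i, c, self.kernel[self._dt_post(j)])
        # timers advance implicitly via t; refractory bookkeeping
        self.refr[self.refr > 0] -= 1
        self.refr[fired] = self.refractory_steps
        self.t += 1
        return fired

    def _bump(self, i, c, dw_eff):
        delta = dw_eff / self.scale_values[i] / self.weight_step
        new = self.codes[i, c] + int(np.round(delta))
        self.codes[i, c] = min(self.code_max, max(self.code_min, new))

    def run(self, raster):
        out = np.zeros((len(raster), self.n_neurons), dtype=bool)
        for t in range(len(raster)):
            out[t] = self.step(raster[t])
        return out


class LayeredDenseOracle:
    """Explicit multi-matrix simulator of a feedforward stack.

    Layer l receives layer l-1's spikes with a one-step delay (the
    neuron -> axon routing delay); external input drives layer 0 in the
    same step.  Optional lateral inhibition on the last layer arrives
    one step after the firing, with zero self-connections.
    """

    def __init__(self, weights, theta, alpha=0.0, v_rest=0.0, refractory_steps=0,
                 inhibition=0.0):
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.sizes = [w.shape[1] for w in self.weights]
        self.theta, self.alpha, self.v_rest = theta, alpha, v_rest
        self.refractory_steps = refractory_steps
        self.inhibition = inhibition
        self.V = [np.full(n, v_rest, dtype=float) for n in self.sizes]
        self.refr = [np.zeros(n, dtype=np.int64) for n in self.sizes]
        self.delayed = [np.zeros(w.shape[0], dtype=bool) for w in self.weights]
        self.delayed_inh = np.zeros(self.sizes[-1], dtype=bool)

    def step(self, external):
        inputs = [np.asarray(external, dtype=bool)] + self.delayed[1:]
        fired_all = []
        for l, w in enumerate(self.weights):
            V, refr = self.V[l], self.refr[l]
            active = refr == 0
            V[active] += (inputs[l].astype(float) @ w)[active]
            if l == len(self.weights) - 1 and self.inhibition:
                inh = self.delayed_inh.astype(float)
                contrib = -abs(self.inhibition) * (inh.sum() - inh)
                V[active] += contrib[active]
            V[active] -= self.alpha * (V[active] - self.v_rest)
            fired = active & (V >= self.theta)
            V[fired] = self.v_rest
            refr[refr > 0] -= 1
            refr[fired] = self.refractory_steps
            fired_all.append(fired)
        self.delayed = [self.delayed[0]] + [f.copy() for f in fired_all[:-1]]
        if self.inhibition:
            self.delayed_inh = fired_all[-1].copy()
        return fired_all

    def run(self, raster):
        outs = [np.zeros((len(raster), n), dtype=bool) for n in self.sizes]
        for t in range(len(raster)):
            fired = self.step(raster[t])
            for l, f in enumerate(fired):
                outs[l][t] = f
        return outs
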