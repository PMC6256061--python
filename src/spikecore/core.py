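"""Discrete-time LIF core with banked synapse memory and offsets.

One ``Core.step`` advances the whole array by a single time step
(1 ms of simulated time): load axon spikes, integrate, leak, fire,
route recurrent spikes, learn, increment timers.

Membrane dynamics follow the leaky integrate-and-fire update

    V_j(t) = V_j(t-1) - alpha * (V_j(t-1) - V_rest)
             + sum_i s_{t,i} * w_pre(i) * w(i, j - O_a(i)),

where the sum runs over spiking axons i whose fan-out window
[O_a(i), O_a(i) + N_f) covers neuron j.  A neuron fires when V >= theta
(inclusive), resets to V_rest and is refractory for R_p steps, during
which it integrates no input (and by default does not leak either).

The first O_n neurons are recurrently wired: neuron i firing at step t
drives axon N_a - O_n + i at step t+1, OR-ed with external input.
Axonal offsets, the neuronal offset and per-axon scale factors are what
let a single R x C synapse array host multi-layer, recurrent and
laterally-inhibited network compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import stdp
from .synapse_memory import BankedSynapseMemory

__all__ = ["CoreConfig", "Core", "StepTrace"]


@dataclass
class CoreConfig:
    """Architectural constants of one core.

    The parallelization factor ``p`` fixes the synapse-memory bank
    count; it changes cycle counts only, never functional results.
    """

    n_axons: int
    n_neurons: int
    n_fanout: int
    p: int = 1
    alpha: float = 0.0
    v_rest: float = 0.0
    theta: float | Sequence[float] = 1.0
    refractory_steps: int = 0
    neuronal_offset: int = 0
    weight_bits: int = 5
    scale_bits: int = 4
    leak_during_refractory: bool = False
    stochastic_stdp: bool = False
    dt: float = 1e-3  # seconds per step

    def __post_init__(self) -> None:
        if self.n_fanout % self.p or self.n_neurons % self.p or self.n_axons % self.p:
            raise ValueError(
                f"p={self.p} must divide n_axons={self.n_axons}, "
                f"n_neurons={self.n_neurons} and n_fanout={self.n_fanout}"
            )
        if self.n_fanout > self.n_neurons:
            raise ValueError("n_fanout cannot exceed n_neurons")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0 <= self.neuronal_offset <= min(self.n_axons, self.n_neurons):
            raise ValueError(
                f"neuronal_offset={self.neuronal_offset} must lie in "
                f"[0, min(n_axons, n_neurons)]"
            )
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be non-negative")
        self.theta_array = np.broadcast_to(
            np.asarray(self.theta, dtype=float), (self.n_neurons,)
        ).copy()


@dataclass
class StepTrace:
    """Per-step event counts feeding the cycle model."""

    spiking_axons: int
    fired_neurons: int
    learn_row_events: int  # timer-0 learn-enabled axons (acausal, row access)
    learn_col_rows: list = field(default_factory=list)  # per fired neuron: incident learn rows


class Core:
    """State and one-step semantics of the simulated core."""

    def __init__(
        self,
        config: CoreConfig,
        weight_codes: np.ndarray | None = None,
        weight_step: float = 1.0,
        scale_codes: np.ndarray | None = None,
        scale_step: float | None = None,
        axonal_offsets: np.ndarray | int = 0,
        kernels: stdp.KernelTable | None = None,
        kernel_id: np.ndarray | int = 0,
        learn_enabled: np.ndarray | bool = False,
        seed: int = 0,
    ):
        cfg = config
        self.config = cfg
        self.rng = np.random.default_rng(seed)

        offs = np.broadcast_to(np.asarray(axonal_offsets, dtype=np.int64), (cfg.n_axons,)).copy()
        if offs.min() < 0 or offs.max() > cfg.n_neurons - cfg.n_fanout:
            raise ValueError(
                f"axonal offsets must lie in [0, {cfg.n_neurons - cfg.n_fanout}]"
            )
        self.axonal_offsets = offs

        if weight_codes is None:
            weight_codes = np.zeros((cfg.n_axons, cfg.n_fanout), dtype=np.int64)
        self.memory = BankedSynapseMemory.from_dense(weight_codes, cfg.p, cfg.weight_bits)
        self.weight_step = float(weight_step)

        if scale_codes is None:
            # neutral scaling: every axon at scale value 1
            scale_codes = np.ones(cfg.n_axons, dtype=np.int64)
            scale_step = 1.0
        self.scale_codes = np.broadcast_to(
            np.asarray(scale_codes, dtype=np.int64), (cfg.n_axons,)
        ).copy()
        if self.scale_codes.min() < 1:
            raise ValueError("scale codes must be >= 1 (zero scale silences an axon)")
        self.scale_step = 1.0 if scale_step is None else float(scale_step)

        self.kernels = kernels if kernels is not None else stdp.KernelTable()
        self.kernel_id = np.broadcast_to(
            np.asarray(kernel_id, dtype=np.int64), (cfg.n_axons,)
        ).copy()
        self.learn_enabled = np.broadcast_to(
            np.asarray(learn_enabled, dtype=bool), (cfg.n_axons,)
        ).copy()

        # dynamic state
        self.V = np.full(cfg.n_neurons, cfg.v_rest, dtype=float)
        self.refractory_remaining = np.zeros(cfg.n_neurons, dtype=np.int64)
        self.neuron_timer = np.full(cfg.n_neurons, stdp.TIMER_MAX, dtype=np.int64)
        self.axon_timer = np.full(cfg.n_axons, stdp.TIMER_MAX, dtype=np.int64)
        self.axon_spikes = np.zeros(cfg.n_axons, dtype=bool)
        self._pending_routed = np.zeros(cfg.n_axons, dtype=bool)
        self.t = 0
        self.trace: list[StepTrace] = []

    # -- derived values -----------------------------------------------------

    @property
    def scale_values(self) -> np.ndarray:
        return self.scale_codes * self.scale_step

    def weight_value(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dense = self.memory.to_dense()
        return dense[rows, cols] * self.weight_step

    # -- phases -------------------------------------------------------------

    def integrate(self, spiking: np.ndarray) -> None:
        """Event-driven synaptic integration for the spiking axons."""
        cfg = self.config
        active = self.refractory_remaining == 0
        for i in spiking:
            j0 = self.axonal_offsets[i]
            window = slice(j0, j0 + cfg.n_fanout)
            contrib = self.scale_values[i] * self.memory.read_row(i) * self.weight_step
            self.V[window] += np.where(active[window], contrib, 0.0)

    def leak(self) -> None:
        cfg = self.config
        if cfg.leak_during_refractory:
            mask = np.ones(cfg.n_neurons, dtype=bool)
        else:
            mask = self.refractory_remaining == 0
        self.V[mask] -= cfg.alpha * (self.V[mask] - cfg.v_rest)

    def fire(self) -> np.ndarray:
        cfg = self.config
        fired = (self.refractory_remaining == 0) & (self.V >= cfg.theta_array)
        self.V[fired] = cfg.v_rest
        self.refractory_remaining[fired] = cfg.refractory_steps
        self.neuron_timer[fired] = 0
        return fired

    def route_spikes(self, fired: np.ndarray) -> np.ndarray:
        """Axon spikes for step t+1 induced by this step's firings."""
        cfg = self.config
        routed = np.zeros(cfg.n_axons, dtype=bool)
        o_n = cfg.neuronal_offset
        if o_n:
            routed[cfg.n_axons - o_n :] = fired[:o_n]
        return routed

    def step(self, external_spikes: np.ndarray | None = None) -> np.ndarray:
        """Advance one time step; returns this step's postsynaptic spikes."""
        cfg = self.config
        if external_spikes is None:
            external_spikes = np.zeros(cfg.n_axons, dtype=bool)
        external_spikes = np.asarray(external_spikes, dtype=bool)
        if external_spikes.shape != (cfg.n_axons,):
            raise ValueError(f"external spike vector must have length {cfg.n_axons}")

        # 1. load axon spikes (external OR routed from last step)
        self.axon_spikes = external_spikes | self._pending_routed
        self.axon_timer[self.axon_spikes] = 0
        spiking = np.flatnonzero(self.axon_spikes)

        # 2-4. integrate, leak, fire
        self.integrate(spiking)
        self.leak()
        was_refractory = self.refractory_remaining > 0
        fired = self.fire()

        # 5. route recurrent spikes for t+1
        self._pending_routed = self.route_spikes(fired)

        # 6. learning
        learn_rows = int(np.count_nonzero(self.learn_enabled & (self.axon_timer == 0)))
        learn_col_rows = []
        for j in np.flatnonzero(fired):
            rel = j - self.axonal_offsets
            n_inc = int(np.count_nonzero(self.learn_enabled & (rel >= 0) & (rel < cfg.n_fanout)))
            if n_inc:
                learn_col_rows.append(n_inc)
        stdp.learn_step(self)

        # 7. timers and refractory bookkeeping
        self.axon_timer = stdp.update_timers(self.axon_timer)
        self.neuron_timer = stdp.update_timers(self.neuron_timer)
        self.refractory_remaining[was_refractory] -= 1

        self.trace.append(
            StepTrace(
                spiking_axons=int(spiking.size),
                fired_neurons=int(np.count_nonzero(fired)),
                learn_row_events=learn_rows,
                learn_col_rows=learn_col_rows,
            )
        )
        self.t += 1
        return fired

    def run(self, raster: np.ndarray) -> np.ndarray:
        """Run T steps from a (T, N_a) boolean input raster.

        Returns the (T, N_n) boolean output raster.
        """
        raster = np.asarray(raster, dtype=bool)
        out = np.zeros((raster.shape[0], self.config.n_neurons), dtype=bool)
        for t in range(raster.shape[0]):
            out[t] = self.step(raster[t])
        return out

    # -- snapshots ----------------------------------------------------------

    def snapshot(self) -> dict:
        """State dump for golden-trace comparisons."""
        return {
            "t": self.t,
            "V": self.V.copy(),
            "neuron_timer": self.neuron_timer.copy(),
            "axon_timer": self.axon_timer.copy(),
            "refractory_remaining": self.refractory_remaining.copy(),
            "weight_codes": self.memory.to_dense(),
        }
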