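"""LUT-kernel STDP driven by saturating 4-bit timers.

Every axon and neuron carries a 4-bit timer counting the steps since its
last spike (saturating at 15).  When a unit's timer is zero — it spiked
this step — the timer of the partner unit *is* the pre/post timing
difference, and a 16-entry signed lookup table maps it to an
effective-weight change:

* pre-then-post (causal): a neuron fires now; each learn-enabled axon
  reaching it contributes kernel[axon_timer].
* post-then-pre (acausal): an axon spikes now; each connected neuron
  that fired earlier (timer > 0) contributes kernel[neuron_timer].

Coincident spikes (both timers zero) are applied once, through the
causal branch with kernel[0].  Because a timer remembers only the
latest spike, the rule is nearest-spike STDP by construction.

The stored code changes by the kernel value divided by the axon's
presynaptic scale value and the weight LSB.  In deterministic mode the
change is rounded; in stochastic mode the code moves by one LSB with
probability min(1, |change|), which keeps the expected update equal to
the real-valued one for sub-LSB changes.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TIMER_MAX",
    "KernelTable",
    "make_kernel",
    "apply_update",
    "update_timers",
    "learn_step",
]

TIMER_MAX = 15  # 4-bit saturating timers
KERNEL_LEN = TIMER_MAX + 1
MAX_KERNELS = 8


class KernelTable:
    """Up to 8 STDP kernels of 16 signed real values each.

    Entry k of a kernel is the effective-weight change for a timing
    difference of k steps; entry 15 also absorbs every older (saturated)
    spike, so it is conventionally 0.
    """

    def __init__(self, kernels: Sequence[Sequence[float]] | None = None):
        self._table = np.zeros((MAX_KERNELS, KERNEL_LEN), dtype=float)
        if kernels is not None:
            for kid, values in enumerate(kernels):
                self.set_kernel(kid, values)

    def set_kernel(self, kernel_id: int, values: Sequence[float]) -> None:
        if not 0 <= kernel_id < MAX_KERNELS:
            raise ValueError(f"kernel id must be 0..{MAX_KERNELS - 1}, got {kernel_id}")
        values = np.asarray(values, dtype=float)
        if values.shape != (KERNEL_LEN,):
            raise ValueError(f"a kernel has exactly {KERNEL_LEN} values, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("kernel values must be finite")
        self._table[kernel_id] = values

    def __getitem__(self, kernel_id: int) -> np.ndarray:
        return self._table[kernel_id]

    @property
    def table(self) -> np.ndarray:
        return self._table

    def save(self, path) -> None:
        np.savetxt(path, self._table, fmt="%.10g", delimiter="\t")

    @classmethod
    def load(cls, path) -> "KernelTable":
        table = np.loadtxt(path, dtype=float, delimiter="\t", ndmin=2)
        return cls(table)


def make_kernel(shape: str, **params) -> np.ndarray:
    """Build one 16-tap kernel.

    shapes:
      exponential : amplitude * exp(-dt / tau)
      simplified  : amplitude for dt < width, 0 after (piecewise constant)
      symmetric   : |amplitude| * exp(-dt / tau)  (sign-free magnitude profile)
      custom      : the 16 ``values`` as given
    An optional ``resolution`` rounds taps to multiples of that
    effective-weight unit.
    """
    dt = np.arange(KERNEL_LEN, dtype=float)
    if shape == "exponential":
        a, tau = params["amplitude"], params["tau"]
        if not (math.isfinite(a) and math.isfinite(tau)) or tau <= 0:
            raise ValueError("exponential kernel needs finite amplitude and tau > 0")
        k = a * np.exp(-dt / tau)
    elif shape == "simplified":
        a, width = params["amplitude"], params.get("width", 4)
        if not math.isfinite(a):
            raise ValueError("simplified kernel needs finite amplitude")
        k = np.where(dt < width, a, 0.0)
    elif shape == "symmetric":
        a, tau = params["amplitude"], params["tau"]
        if not (math.isfinite(a) and math.isfinite(tau)) or tau <= 0:
            raise ValueError("symmetric kernel needs finite amplitude and tau > 0")
        k = abs(a) * np.exp(-dt / tau)
    elif shape == "custom":
        k = np.asarray(params["values"], dtype=float)
        if k.shape != (KERNEL_LEN,):
            raise ValueError(f"custom kernel needs {KERNEL_LEN} values")
        if not np.all(np.isfinite(k)):
            raise ValueError("kernel values must be finite")
    else:
        raise ValueError(f"unknown kernel shape {shape!r}")
    resolution = params.get("resolution")
    if resolution:
        k = np.round(k / resolution) * resolution
    return k


def apply_update(
    code: np.ndarray,
    delta_code_real: np.ndarray,
    mode: Literal["deterministic", "stochastic"],
    rng: np.random.Generator | None,
    code_min: int,
    code_max: int,
) -> np.ndarray:
    """Apply a real-valued code change to stored codes, saturating.

    deterministic: code + round(delta); stochastic: code + sign(delta)
    with probability min(1, |delta|).  Results clip to
    [code_min, code_max].
    """
    code = np.asarray(code, dtype=np.int64)
    delta = np.asarray(delta_code_real, dtype=float)
    if mode == "deterministic":
        moved = code + np.round(delta).astype(np.int64)
    elif mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        p = np.minimum(1.0, np.abs(delta))
        hit = rng.random(size=np.broadcast_shapes(code.shape, delta.shape)) < p
        moved = code + hit * np.sign(delta).astype(np.int64)
    else:
        raise ValueError(f"unknown update mode {mode!r}")
    return np.clip(moved, code_min, code_max)


def update_timers(timers: np.ndarray) -> np.ndarray:
    """End-of-step increment with saturation at 15."""
    return np.minimum(timers + 1, TIMER_MAX)


def learn_step(core) -> None:
    """One learning phase on a :class:`~spikecore.core.Core`.

    Must run after the fire phase (timers of this step's spikes are 0)
    and before the end-of-step timer increment.  Touches only synapses
    incident to a unit with timer 0 this step; each synapse is updated
    at most once (the causal branch owns coincident pairs).
    """
    cfg = core.config
    if not np.any(core.learn_enabled):
        return
    if core.weight_step <= 0:
        raise ValueError("learning requires a positive weight_step")
    kernel = core.kernels.table[core.kernel_id, :]  # (N_a, 16) per-axon LUT

    rows_list, cols_list, delta_list = [], [], []

    # causal branch: neurons that fired this step
    fired = np.flatnonzero(core.neuron_timer == 0)
    for j in fired:
        rel = j - core.axonal_offsets
        pre = np.flatnonzero(core.learn_enabled & (rel >= 0) & (rel < cfg.n_fanout))
        if pre.size:
            rows_list.append(pre)
            cols_list.append(rel[pre])
            delta_list.append(kernel[pre, core.axon_timer[pre]])

    # acausal branch: axons that spiked this step, partners that fired earlier
    spiking = np.flatnonzero(core.learn_enabled & (core.axon_timer == 0))
    for i in spiking:
        j0 = core.axonal_offsets[i]
        post_timer = core.neuron_timer[j0 : j0 + cfg.n_fanout]
        cols = np.flatnonzero(post_timer > 0)
        if cols.size:
            rows_list.append(np.full(cols.size, i))
            cols_list.append(cols)
            delta_list.append(kernel[i, post_timer[cols]])

    if not rows_list:
        return
    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    dw_eff = np.concatenate(delta_list)
    # stored-code change: kernel value / presynaptic scale / weight LSB
    delta_code = dw_eff / core.scale_values[rows] / core.weight_step

    mem = core.memory
    banks_idx = (rows + cols) % mem.B
    addrs = (mem.C * rows + cols) // mem.B
    current = mem.banks[banks_idx, addrs]
    mode = "stochastic" if cfg.stochastic_stdp else "deterministic"
    mem.banks[banks_idx, addrs] = apply_update(
        current, delta_code, mode, core.rng, mem.code_min, mem.code_max
    )
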