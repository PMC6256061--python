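"""Compile layered network descriptions onto a single core.

A core exposes one R x C synapse array, per-axon offsets and a
neuronal offset; multi-layer, recurrent and laterally-inhibited
topologies are all expressed by placing each layer's weights in a block
of rows and pointing those rows' axonal offsets at the layer's neuron
block.  Hidden-layer neurons are placed first so the neuronal offset
routes their spikes back onto the trailing axons one step later.

Axon layout      : [ external inputs of layer 1 | padding | recurrent axons ]
Neuron layout    : [ hidden neurons (routed back) | final-layer neurons ]

Fan-out wider than N_f is handled explicitly by axon splitting: m axons
with offsets O, O + N_f, ... receive the same input, conceptually one
axon reaching m*N_f consecutive neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Core, CoreConfig
from . import stdp

__all__ = ["LayerSpec", "ComposedNetwork", "compose_feedforward", "add_lateral_inhibition", "split_axon"]


@dataclass
class LayerSpec:
    """One dense layer: n_in x n_out real weights and learning flags."""

    n_in: int
    n_out: int
    weights: np.ndarray | None = None  # real weights, codes assigned via weight_step
    learn: bool = False
    kernel_id: int = 0
    inhibitory: float = 0.0  # |w| of lateral inhibition within the output layer

    def __post_init__(self) -> None:
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError("layer sizes must be positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_in, self.n_out):
                raise ValueError(
                    f"weights shape {self.weights.shape} != ({self.n_in}, {self.n_out})"
                )


@dataclass
class ComposedNetwork:
    """A compiled core plus the bookkeeping to drive and read it."""

    core: Core
    input_axons: np.ndarray  # physical axon ids receiving external input
    layer_neurons: list  # per layer: np.ndarray of neuron ids
    wasted_cells: int = 0

    def external_raster(self, input_raster: np.ndarray) -> np.ndarray:
        """Map a (T, n_in) logical input raster onto physical axons."""
        input_raster = np.asarray(input_raster, dtype=bool)
        T = input_raster.shape[0]
        full = np.zeros((T, self.core.config.n_axons), dtype=bool)
        for logical, phys in enumerate(self.input_axons):
            for a in np.atleast_1d(phys):
                full[:, a] |= input_raster[:, logical]
        return full

    def run(self, input_raster: np.ndarray) -> list:
        """Run and return per-layer (T, n_out) output rasters."""
        out = self.core.run(self.external_raster(input_raster))
        return [out[:, ids] for ids in self.layer_neurons]


def _round_up(n: int, m: int) -> int:
    return ((n + m - 1) // m) * m


def compose_feedforward(
    layers: list[LayerSpec],
    p: int = 1,
    weight_step: float | None = None,
    weight_bits: int = 5,
    spare_axons: int = 0,
    spare_neurons: int = 0,
    theta: float = 1.0,
    alpha: float = 0.0,
    refractory_steps: int = 0,
    seed: int = 0,
    **core_kwargs,
) -> ComposedNetwork:
    """Compile a feedforward stack (optionally laterally inhibited).

    Core dimensions are derived from the stack and padded to multiples
    of p; padding rows/columns hold zero weights and are reported as
    wasted cells.  Real weights are converted to codes with
    ``weight_step`` (default: max |w| mapped to the top code).
    """
    if not layers:
        raise ValueError("empty layer list")
    for a, b in zip(layers, layers[1:]):
        if a.n_out != b.n_in:
            raise ValueError(f"layer sizes do not chain: {a.n_out} -> {b.n_in}")

    widths = [l.n_out for l in layers]
    inhibited = [l for l in layers if l.inhibitory]
    # neuron blocks: hidden layers (and inhibited layers, which need
    # recurrence) first, purely-output layers last
    needs_route = [
        (idx < len(layers) - 1) or bool(l.inhibitory) for idx, l in enumerate(layers)
    ]
    order = [i for i, r in enumerate(needs_route) if r] + [
        i for i, r in enumerate(needs_route) if not r
    ]
    n_fanout = _round_up(max(widths), p)
    blocks: dict[int, np.ndarray] = {}
    cursor = 0
    for idx in order:
        blocks[idx] = np.arange(cursor, cursor + layers[idx].n_out)
        cursor += layers[idx].n_out
    o_n = sum(layers[i].n_out for i in range(len(layers)) if needs_route[i])

    n_neurons = _round_up(max(cursor + spare_neurons, n_fanout), p)
    # make sure every block start is a legal axonal offset
    max_start = max(int(b[0]) for b in blocks.values())
    n_neurons = _round_up(max(n_neurons, max_start + n_fanout), p)

    # axon blocks: external inputs first, recurrent axons at the tail
    n_ext = layers[0].n_in
    n_axons = _round_up(n_ext + spare_axons + o_n, p)
    if o_n > min(n_axons, n_neurons):
        n_neurons = _round_up(o_n, p)

    # recurrent axon of routed neuron k (global neuron id k < o_n) is
    # n_axons - o_n + k
    def routed_axon(neuron_id: int) -> int:
        return n_axons - o_n + neuron_id

    W_codes = np.zeros((n_axons, n_fanout), dtype=np.int64)
    offsets = np.zeros(n_axons, dtype=np.int64)
    learn = np.zeros(n_axons, dtype=bool)
    kid = np.zeros(n_axons, dtype=np.int64)

    # scale real weights to codes
    all_w = [np.abs(l.weights).max() for l in layers if l.weights is not None]
    all_w += [abs(l.inhibitory) for l in layers if l.inhibitory]
    w_max = max(all_w) if all_w else 1.0
    if weight_step is None:
        code_max = (1 << (weight_bits - 1)) - 1
        weight_step = (w_max / code_max) if w_max > 0 else 1.0

    def to_code(w: np.ndarray) -> np.ndarray:
        code_max = (1 << (weight_bits - 1)) - 1
        code_min = -(1 << (weight_bits - 1))
        return np.clip(np.round(w / weight_step), code_min, code_max).astype(np.int64)

    rng = np.random.default_rng(seed)
    for idx, layer in enumerate(layers):
        W = layer.weights
        if W is None:
            W = rng.normal(0.0, 1.0, size=(layer.n_in, layer.n_out))
        if layer.n_out > n_fanout:
            raise ValueError(
                f"layer {idx} width {layer.n_out} exceeds fan-out {n_fanout}; "
                "use split_axon to extend fan-out"
            )
        if idx == 0:
            axon_ids = np.arange(n_ext)
        else:
            axon_ids = np.array([routed_axon(k) for k in blocks[idx - 1]])
        offsets[axon_ids] = blocks[idx][0]
        W_codes[axon_ids, : layer.n_out] = to_code(W)
        learn[axon_ids] = layer.learn
        kid[axon_ids] = layer.kernel_id

    cfg = CoreConfig(
        n_axons=n_axons,
        n_neurons=n_neurons,
        n_fanout=n_fanout,
        p=p,
        theta=theta,
        alpha=alpha,
        refractory_steps=refractory_steps,
        neuronal_offset=o_n,
        weight_bits=weight_bits,
        **core_kwargs,
    )
    core = Core(
        cfg,
        weight_codes=W_codes,
        weight_step=weight_step,
        axonal_offsets=offsets,
        kernel_id=kid,
        learn_enabled=learn,
        seed=seed,
    )
    net = ComposedNetwork(
        core=core,
        input_axons=np.arange(n_ext, dtype=np.int64),
        layer_neurons=[blocks[i] for i in range(len(layers))],
        wasted_cells=int(n_axons * n_fanout - sum(l.n_in * l.n_out for l in layers)),
    )
    for idx, layer in enumerate(layers):
        if layer.inhibitory:
            add_lateral_inhibition(net, idx, layer.inhibitory)
    return net


def add_lateral_inhibition(net: ComposedNetwork, layer_index: int, weight: float) -> ComposedNetwork:
    """Wire negative recurrent synapses within one layer's neuron block.

    Each neuron's recurrent axon depresses every *other* neuron of the
    layer by |weight| one step after it fires; self-connections are
    zero (a neuron must not inhibit itself).
    """
    core = net.core
    cfg = core.config
    neurons = net.layer_neurons[layer_index]
    width = len(neurons)
    if weight == 0.0:
        return net
    if layer_index != len(net.layer_neurons) - 1:
        # a hidden neuron's single recurrent axon already carries its
        # feedforward row; inhibiting it too would need axon splitting
        raise ValueError("lateral inhibition is supported on the final layer only")
    if width > cfg.n_fanout:
        raise ValueError(f"layer width {width} exceeds fan-out {cfg.n_fanout}")
    o_n = cfg.neuronal_offset
    if neurons[-1] >= o_n:
        raise ValueError("layer neurons are not routed back to axons (outside O_n)")
    code = -abs(int(round(abs(weight) / core.weight_step)))
    if code < core.memory.code_min:
        raise ValueError("inhibitory weight exceeds the signed code range")
    dense = core.memory.to_dense()
    block_start = int(neurons[0])
    for k, j in enumerate(neurons):
        axon = cfg.n_axons - o_n + j
        core.axonal_offsets[axon] = block_start
        row = np.zeros(cfg.n_fanout, dtype=np.int64)
        row[:width] = code
        row[k] = 0  # no self-inhibition
        dense[axon] = row
    core.memory = type(core.memory).from_dense(dense, cfg.p, cfg.weight_bits)
    return net


def split_axon(net: ComposedNetwork, logical_input: int, copies: int) -> ComposedNetwork:
    """Extend one input axon's reach to copies * N_f consecutive neurons.

    Uses the duplicate-axon pattern: ``copies`` physical axons with
    offsets O, O + N_f, ... receive the same external input.  The
    caller distributes the wide weight row across the copies' rows.
    """
    core = net.core
    cfg = core.config
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if copies == 1:
        return net
    base = np.atleast_1d(net.input_axons[logical_input])[0]
    base_off = int(core.axonal_offsets[base])
    if base_off + copies * cfg.n_fanout > cfg.n_neurons:
        raise ValueError(
            f"{copies} copies of fan-out {cfg.n_fanout} exceed {cfg.n_neurons} neurons"
        )
    used = set()
    for phys in np.asarray(net.input_axons, dtype=object):
        used.update(np.atleast_1d(phys).tolist())
    free = [a for a in range(cfg.n_axons) if a not in used and a < cfg.n_axons - cfg.neuronal_offset]
    if len(free) < copies - 1:
        raise ValueError("not enough free axons for the requested split")
    phys = [int(base)] + [int(a) for a in free[: copies - 1]]
    for m, a in enumerate(phys):
        core.axonal_offsets[a] = base_off + m * cfg.n_fanout
    inputs = list(net.input_axons)
    inputs[logical_input] = np.asarray(phys, dtype=np.int64)
    net.input_axons = np.asarray(inputs, dtype=object)
    return net
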