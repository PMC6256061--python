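"""Seeded generators for simulator inputs.

Everything here is a pure function of its arguments and the seed:
Bernoulli-per-step Poisson spike rasters (the core accepts at most one
spike per axon per step, so rates are clamped to one spike/step),
random weight matrices with a controllable per-axon magnitude spread,
and fully specified toy cores with input rasters for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Core, CoreConfig
from . import stdp

__all__ = ["PoissonSpec", "poisson_spikes", "structured_weights", "random_core"]

DT = 1e-3  # one time step represents 1 ms


@dataclass
class PoissonSpec:
    """Per-axon rates in Hz over a number of 1 ms steps."""

    intensities: np.ndarray
    duration: int
    seed: int = 0
    dt: float = DT

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("spike rates must be non-negative")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


def poisson_spikes(spec: PoissonSpec) -> np.ndarray:
    """(duration, n_axons) boolean raster; p(spike) = min(1, rate*dt)."""
    rng = np.random.default_rng(spec.seed)
    p = np.minimum(1.0, spec.intensities * spec.dt)
    return rng.random((spec.duration, spec.intensities.size)) < p


def structured_weights(
    R: int, C: int, axon_scale_spread: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Random R x C weights whose rows differ in magnitude.

    Row i is c_i times i.i.d. standard-normal noise with the c_i
    log-spaced over e**(+-spread/2), emulating trained weight matrices
    where some axons carry systematically stronger synapses.  Spread 0
    gives exchangeable rows.
    """
    if axon_scale_spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=(R, C))
    c = np.exp(np.linspace(-axon_scale_spread / 2, axon_scale_spread / 2, R))
    return c[:, None] * base


def random_core(
    n_axons: int = 16,
    n_neurons: int = 16,
    n_fanout: int = 8,
    p: int = 2,
    duration: int = 50,
    seed: int = 0,
    rate_hz: float = 100.0,
    learn: bool = False,
    neuronal_offset: int = 0,
    **config_kwargs,
) -> tuple[Core, np.ndarray]:
    """A seeded toy core plus a Poisson input raster for oracle tests."""
    rng = np.random.default_rng(seed)
    cfg = CoreConfig(
        n_axons=n_axons,
        n_neurons=n_neurons,
        n_fanout=n_fanout,
        p=p,
        alpha=config_kwargs.pop("alpha", 0.25),
        theta=config_kwargs.pop("theta", 0.5),
        refractory_steps=config_kwargs.pop("refractory_steps", 2),
        neuronal_offset=neuronal_offset,
        **config_kwargs,
    )
    code_max = (1 << (cfg.weight_bits - 1)) - 1
    codes = rng.integers(-code_max, code_max + 1, size=(n_axons, n_fanout))
    offsets = rng.integers(0, n_neurons - n_fanout + 1, size=n_axons)
    scale_codes = rng.integers(1, (1 << cfg.scale_bits) + 1, size=n_axons)
    kernels = stdp.KernelTable(
        [stdp.make_kernel("exponential", amplitude=0.5, tau=4.0)]
    )
    core = Core(
        cfg,
        weight_codes=codes,
        weight_step=1.0 / code_max,
        scale_codes=scale_codes,
        scale_step=1.0 / (1 << cfg.scale_bits),
        axonal_offsets=offsets,
        kernels=kernels,
        kernel_id=0,
        learn_enabled=learn,
        seed=seed,
    )
    raster = poisson_spikes(
        PoissonSpec(np.full(n_axons, rate_hz), duration, seed=seed + 1)
    )
    return core, raster
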