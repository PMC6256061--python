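import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from spikecore import Core, CoreConfig, KernelTable, make_kernel

from oracles import DenseCoreOracle


def make_pair(
    n_axons=16,
    n_neurons=16,
    n_fanout=8,
    p=2,
    theta=0.5,
    alpha=0.25,
    refractory_steps=2,
    neuronal_offset=0,
    learn=False,
    kernel=None,
    seed=0,
    scale_bits=4,
    weight_bits=5,
):
    """A simulator core and its dense oracle sharing one random setup."""
    rng = np.random.default_rng(seed)
    code_max = (1 << (weight_bits - 1)) - 1
    codes = rng.integers(-code_max, code_max + 1, size=(n_axons, n_fanout))
    offsets = rng.integers(0, n_neurons - n_fanout + 1, size=n_axons)
    scale_codes = rng.integers(1, (1 << scale_bits) + 1, size=n_axons)
    scale_step = 1.0 / (1 << scale_bits)
    weight_step = 1.0 / code_max
    if kernel is None and learn:
        kernel = make_kernel("custom", values=np.r_[0.4, 0.2, 0.1, np.full(12, 0.05), 0.0])
    cfg = CoreConfig(
        n_axons=n_axons,
        n_neurons=n_neurons,
        n_fanout=n_fanout,
        p=p,
        alpha=alpha,
        theta=theta,
        refractory_steps=refractory_steps,
        neuronal_offset=neuronal_offset,
        weight_bits=weight_bits,
        scale_bits=scale_bits,
    )
    core = Core(
        cfg,
        weight_codes=codes.copy(),
        weight_step=weight_step,
        scale_codes=scale_codes,
        scale_step=scale_step,
        axonal_offsets=offsets,
        kernels=KernelTable([kernel]) if kernel is not None else None,
        kernel_id=0,
        learn_enabled=learn,
        seed=seed,
    )
    oracle = DenseCoreOracle(
        n_axons,
        n_neurons,
        n_fanout,
        codes.copy(),
        weight_step,
        scale_codes * scale_step,
        offsets,
        theta,
        alpha=alpha,
        refractory_steps=refractory_steps,
        neuronal_offset=neuronal_offset,
        kernel=kernel if learn else None,
        learn_enabled=learn,
        code_bits=weight_bits,
    )
    return core, oracle


@pytest.fixture
def toy_pair():
    return make_pair()
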