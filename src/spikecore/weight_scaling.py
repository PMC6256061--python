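"""Presynaptic weight scaling and fixed-point weight quantization.

The core stores each synapse as a low-precision signed code and each
axon as a small unsigned scale code; the effective weight used during
integration is the product

    w_eff(i, j) = w_pre(i) * w(i, j)
               = scale_code[i] * scale_step  *  weight_code[i, j] mapped
                 through a linear level grid.

Rows of a trained weight matrix tend to share a magnitude (an axon's
synapses are similarly strong), so dividing each row by a per-axon
scale before quantizing spends the weight bits on the row's *shape*
rather than its magnitude.  The per-axon scale is set proportional to
the RMS (or mean absolute value) of that axon's weights and itself
quantized to ``scale_bits`` unsigned levels 1..2**scale_bits (zero is
excluded: a zero scale would silence the axon and break the STDP code
update, which divides the kernel value by the scale).

The module also provides the synapse-memory bit accounting
(#synapses*b + #axons*b_pre) and the minimum-step ratio 2**b_pre by
which scaling shrinks the smallest representable effective weight
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "QuantizerConfig",
    "ScaledWeightSet",
    "compute_scale_factors",
    "quantize_linear",
    "grid_search_range",
    "apply_presynaptic_scaling",
    "memory_bits",
    "min_step_ratio",
    "group_dispersion_stats",
]


@dataclass
class QuantizerConfig:
    """Quantizer settings: weight bits b, scale bits b_pre, level range."""

    weight_bits: int = 5
    scale_bits: int = 4  # 0 disables presynaptic scaling
    range: tuple[float, float] | None = None
    scale_method: Literal["rms", "mean_abs"] = "rms"

    def __post_init__(self) -> None:
        if not 1 <= self.weight_bits <= 8:
            raise ValueError(f"weight_bits must be in 1..8, got {self.weight_bits}")
        if not 0 <= self.scale_bits <= 8:
            raise ValueError(f"scale_bits must be in 0..8, got {self.scale_bits}")


@dataclass
class ScaledWeightSet:
    """Quantized weights plus per-axon scale codes.

    effective weight(i, j) = scale_codes[i]*scale_step * level(weight_codes[i, j])
    where level(q) = w_min + (q - code_min) * weight_step.
    """

    scale_codes: np.ndarray  # unsigned, 1..2**scale_bits
    scale_step: float
    weight_codes: np.ndarray  # signed, R x C
    weight_step: float
    weight_bits: int
    scale_bits: int
    w_min: float = 0.0  # real value of the lowest quantization level

    @property
    def scale_values(self) -> np.ndarray:
        return self.scale_codes * self.scale_step

    def weight_values(self) -> np.ndarray:
        """Per-synapse level values (before the per-axon scale)."""
        code_min = -(1 << (self.weight_bits - 1))
        return self.w_min + (self.weight_codes - code_min) * self.weight_step

    def effective_weights(self) -> np.ndarray:
        return self.scale_values[:, None] * self.weight_values()


def compute_scale_factors(
    W: np.ndarray, b_pre: int, method: Literal["rms", "mean_abs"] = "rms"
) -> tuple[np.ndarray, float]:
    """Per-axon scale codes and the real value of one scale-code unit.

    The raw scale of axon i is the RMS (or mean |w|) of row i; codes are
    round(raw/scale_step) clipped to 1..2**b_pre with
    scale_step = max_i raw(i) / 2**b_pre, so the largest row maps to the
    top code.  An all-zero row is degenerate (no information about the
    axon's magnitude); its code is clamped to 1 with a warning.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if b_pre < 1:
        raise ValueError("b_pre must be >= 1; use memory_bits(b_pre=0) for disabled scaling")
    if method == "rms":
        raw = np.sqrt(np.mean(W**2, axis=1))
    elif method == "mean_abs":
        raw = np.mean(np.abs(W), axis=1)
    else:
        raise ValueError(f"unknown scale method {method!r}")
    top = raw.max()
    if top == 0.0:
        warnings.warn("all rows are zero; scale codes clamped to 1", stacklevel=2)
        return np.ones(W.shape[0], dtype=np.int64), 0.0
    scale_step = top / (1 << b_pre)
    codes = np.clip(np.round(raw / scale_step), 1, 1 << b_pre).astype(np.int64)
    if np.any(raw == 0.0):
        warnings.warn("zero row(s) encountered; scale code clamped to 1", stacklevel=2)
    return codes, scale_step


def quantize_linear(
    W: np.ndarray, b: int, range: tuple[float, float]
) -> tuple[np.ndarray, float]:
    """Clip to [w_min, w_max] and round to 2**b evenly spaced levels.

    Returns signed codes in [-2**(b-1), 2**(b-1)-1] (level value
    w_min + (code - code_min)*step) and the step (w_max-w_min)/(2**b-1).
    Rounding ties go to the level nearer zero, so the quantizer commutes
    with a sign flip of a symmetric range.
    """
    w_min, w_max = range
    if not w_min < w_max:
        raise ValueError(f"degenerate range ({w_min}, {w_max})")
    W = np.asarray(W, dtype=float)
    n_levels = 1 << b
    step = (w_max - w_min) / (n_levels - 1)
    pos = (np.clip(W, w_min, w_max) - w_min) / step
    lo = np.floor(pos)
    frac = pos - lo
    q = np.where(frac > 0.5, lo + 1, lo)
    # half-way ties: pick the level with the smaller |value|
    tie = np.isclose(frac, 0.5)
    if np.any(tie):
        v_lo = w_min + lo * step
        v_hi = v_lo + step
        q = np.where(tie & (np.abs(v_hi) < np.abs(v_lo)), lo + 1, q)
        q = np.where(tie & ~(np.abs(v_hi) < np.abs(v_lo)), lo, q)
    q = np.clip(q, 0, n_levels - 1).astype(np.int64)
    codes = q - (1 << (b - 1))
    return codes, step


def reconstruct(codes: np.ndarray, b: int, step: float, w_min: float) -> np.ndarray:
    """Level values of signed codes produced by :func:`quantize_linear`."""
    return w_min + (codes + (1 << (b - 1))) * step


def _mse_score(W: np.ndarray, b: int, rng: tuple[float, float]) -> float:
    codes, step = quantize_linear(W, b, rng)
    return -float(np.mean((reconstruct(codes, b, step, rng[0]) - W) ** 2))


def grid_search_range(
    W: np.ndarray,
    b: int,
    candidates: Sequence[tuple[float, float]],
    score: Callable[[np.ndarray, int, tuple[float, float]], float] | None = None,
) -> tuple[float, float]:
    """Pick the quantization range maximizing a score over candidates.

    The default score is the negative mean-squared reconstruction error;
    a task-level evaluator (e.g. classification accuracy) can be passed
    instead.  Ties keep the first candidate.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    if score is None:
        score = _mse_score
    best, best_s = None, -np.inf
    for cand in candidates:
        s = score(np.asarray(W, dtype=float), b, tuple(cand))
        if s > best_s:
            best, best_s = tuple(cand), s
    return best


def apply_presynaptic_scaling(
    W: np.ndarray,
    b: int,
    b_pre: int,
    method: Literal["rms", "mean_abs"] = "rms",
) -> ScaledWeightSet:
    """Factor W into per-axon scales and a quantized residual matrix.

    Row i is divided by its quantized scale value, and the residual
    matrix is linearly quantized on a symmetric range covering its
    extremes.  Reconstruction is scale_value(i) * residual level.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if np.all(W == 0.0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scale_codes, _ = compute_scale_factors(np.ones_like(W), b_pre, method)
        return ScaledWeightSet(
            scale_codes=scale_codes,
            scale_step=0.0,
            weight_codes=np.zeros(W.shape, dtype=np.int64),
            weight_step=0.0,
            weight_bits=b,
            scale_bits=b_pre,
            w_min=0.0,
        )
    scale_codes, scale_step = compute_scale_factors(W, b_pre, method)
    scale_values = scale_codes * scale_step
    residual = W / scale_values[:, None]
    m = float(np.max(np.abs(residual)))
    codes, step = quantize_linear(residual, b, (-m, m))
    return ScaledWeightSet(
        scale_codes=scale_codes,
        scale_step=scale_step,
        weight_codes=codes,
        weight_step=step,
        weight_bits=b,
        scale_bits=b_pre,
        w_min=-m,
    )


def memory_bits(n_axons: int, n_synapses: int, b: int, b_pre: int = 0) -> int:
    """Total synapse-memory bits: n_synapses*b + n_axons*b_pre.

    With scaling disabled (b_pre=0) the scale term vanishes.
    """
    if min(n_axons, n_synapses, b, b_pre) < 0:
        raise ValueError("arguments must be non-negative")
    return n_synapses * b + n_axons * b_pre


def min_step_ratio(b_pre: int) -> int:
    """Largest/smallest effective minimum weight change under scaling.

    Scale codes are the uniformly spaced nonzero integers 1..2**b_pre,
    so an axon at the smallest scale changes its effective weight in
    steps 2**b_pre times finer than an axon at the largest scale (which
    matches the unscaled step).  b_pre=0 (scaling disabled) gives 1.
    """
    if b_pre < 0:
        raise ValueError("b_pre must be non-negative")
    return 1 << b_pre


def group_dispersion_stats(W: np.ndarray) -> dict[str, float]:
    """Spread across axon rows vs neuron columns of per-group magnitudes.

    For each pre-group (row: all synapses from one axon) and post-group
    (column: all synapses onto one neuron), compute the group's mean
    absolute weight and RMS, and return the standard deviation of those
    summaries across groups.  A pre-group sigma much larger than the
    post-group sigma is the empirical signature that a per-axon scale
    captures real structure.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.size == 0:
        raise ValueError("empty matrix")
    return {
        "pre_sigma_mean_abs": float(np.std(np.mean(np.abs(W), axis=1))),
        "post_sigma_mean_abs": float(np.std(np.mean(np.abs(W), axis=0))),
        "pre_sigma_rms": float(np.std(np.sqrt(np.mean(W**2, axis=1)))),
        "post_sigma_rms": float(np.std(np.sqrt(np.mean(W**2, axis=0)))),
    }
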