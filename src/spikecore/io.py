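"""On-disk formats and run configuration.

Formats are plain delimited text throughout:

* weight matrices — one header line ``# R=.. C=.. bits=.. step=..``
  followed by tab-separated rows (rows = axons, columns = fan-out
  slots);
* spike events — AER-like ``t,id`` lines, one event per line, ordered
  by time step;
* step traces — tab-separated per-step event counts for the cycle
  model;
* run configuration — a single YAML document; every source of
  randomness is a named seed in the config, so a run is reproducible
  from the config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import Core, CoreConfig, StepTrace
from . import stdp

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "build_core",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_spike_events",
    "write_spike_events",
    "events_to_raster",
    "raster_to_events",
    "read_trace",
    "write_trace",
]


# -- weight matrices --------------------------------------------------------

def write_weight_matrix(path, W: np.ndarray, bits: int = 0, step: float = 0.0) -> None:
    W = np.atleast_2d(np.asarray(W))
    fmt = "%d" if np.issubdtype(W.dtype, np.integer) else "%.10g"
    np.savetxt(
        path, W, fmt=fmt, delimiter="\t",
        header=f"R={W.shape[0]} C={W.shape[1]} bits={bits} step={step!r}",
    )


def read_weight_matrix(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(kv.split("=", 1) for kv in header.split())
    W = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    meta = {
        "R": int(meta.get("R", W.shape[0])),
        "C": int(meta.get("C", W.shape[1])),
        "bits": int(meta.get("bits", 0)),
        "step": float(meta.get("step", "0").strip("'\"")),
    }
    if W.shape != (meta["R"], meta["C"]):
        raise ValueError(f"weight matrix shape {W.shape} does not match header {meta}")
    return W, meta


# -- spike events -----------------------------------------------------------

def write_spike_events(path, events: np.ndarray) -> None:
    """Events as (t, id) integer pairs, one 't,id' line each."""
    events = np.asarray(events, dtype=np.int64).reshape(-1, 2)
    with open(path, "w") as fh:
        fh.write("t,id\n")
        for t, i in events:
            fh.write(f"{t},{i}\n")


def read_spike_events(path) -> np.ndarray:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()[1:] if ln.strip()]
    if not lines:
        return np.zeros((0, 2), dtype=np.int64)
    return np.array([[int(v) for v in ln.split(",")] for ln in lines], dtype=np.int64)


def raster_to_events(raster: np.ndarray) -> np.ndarray:
    t, i = np.nonzero(np.asarray(raster, dtype=bool))
    return np.column_stack([t, i]).astype(np.int64)


def events_to_raster(events: np.ndarray, duration: int, n_units: int) -> np.ndarray:
    raster = np.zeros((duration, n_units), dtype=bool)
    events = np.asarray(events, dtype=np.int64).reshape(-1, 2)
    if events.size:
        if events[:, 0].max(initial=0) >= duration or events[:, 1].max(initial=0) >= n_units:
            raise ValueError("spike event outside the raster dimensions")
        raster[events[:, 0], events[:, 1]] = True
    return raster


# -- step traces ------------------------------------------------------------

def write_trace(path, trace: list[StepTrace]) -> None:
    with open(path, "w") as fh:
        fh.write("step\tspiking_axons\tfired_neurons\tlearn_row_events\tlearn_col_rows\n")
        for t, st in enumerate(trace):
            rows = ",".join(str(r) for r in st.learn_col_rows)
            fh.write(f"{t}\t{st.spiking_axons}\t{st.fired_neurons}\t{st.learn_row_events}\t{rows}\n")


def read_trace(path) -> list[StepTrace]:
    trace = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            _, spk, fired, lrow, lcols = line.rstrip("\n").split("\t")
            trace.append(
                StepTrace(
                    spiking_axons=int(spk),
                    fired_neurons=int(fired),
                    learn_row_events=int(lrow),
                    learn_col_rows=[int(r) for r in lcols.split(",") if r],
                )
            )
    return trace


# -- run configuration ------------------------------------------------------

_CORE_FIELDS = {
    "n_axons", "n_neurons", "n_fanout", "p", "alpha", "v_rest", "theta",
    "refractory_steps", "neuronal_offset", "weight_bits", "scale_bits",
    "leak_during_refractory", "stochastic_stdp",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    core: dict
    steps: int = 100
    seed: int = 0
    axonal_offsets: list | int = 0
    weight_step: float = 1.0
    weights_file: str | None = None
    scale_codes: list | int = 1
    scale_step: float = 1.0
    kernels_file: str | None = None
    kernel_id: list | int = 0
    learn_enabled: list | bool = False
    input: dict = field(default_factory=dict)
    transposable: bool = True
    base_dir: Path = field(default_factory=Path)

    def core_config(self) -> CoreConfig:
        unknown = set(self.core) - _CORE_FIELDS
        if unknown:
            raise ValueError(f"unknown core field(s): {sorted(unknown)}")
        return CoreConfig(**self.core)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Validation failures name the offending field; the core invariants
    (divisibility by p, offset ranges) are enforced by building the
    CoreConfig and the Core eagerly once.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "core" not in doc:
        raise ValueError("config must be a mapping with a 'core' section")
    known = {f for f in RunConfig.__dataclass_fields__ if f != "base_dir"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    rc = RunConfig(**doc, base_dir=path.parent)
    build_core(rc)  # surfaces invariant violations with field context
    return rc


def save_config(rc: RunConfig, path) -> None:
    doc = {
        f: getattr(rc, f)
        for f in RunConfig.__dataclass_fields__
        if f != "base_dir"
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def build_core(rc: RunConfig) -> Core:
    """Instantiate the simulated core described by a RunConfig."""
    cfg = rc.core_config()
    if rc.weights_file is not None:
        W, meta = read_weight_matrix(rc.base_dir / rc.weights_file)
        codes = W.astype(np.int64)
        weight_step = meta["step"] or rc.weight_step
    else:
        codes = None
        weight_step = rc.weight_step
    kernels = (
        stdp.KernelTable.load(rc.base_dir / rc.kernels_file)
        if rc.kernels_file
        else None
    )
    scale_codes = np.broadcast_to(np.asarray(rc.scale_codes, dtype=np.int64), (cfg.n_axons,))
    try:
        return Core(
            cfg,
            weight_codes=codes,
            weight_step=weight_step,
            scale_codes=scale_codes,
            scale_step=rc.scale_step,
            axonal_offsets=rc.axonal_offsets,
            kernels=kernels,
            kernel_id=rc.kernel_id,
            learn_enabled=rc.learn_enabled,
            seed=rc.seed,
        )
    except ValueError as err:
        raise ValueError(f"invalid run configuration: {err}") from err


def input_raster(rc: RunConfig) -> np.ndarray:
    """Build the (steps, N_a) external input raster a config describes."""
    from .fixtures import PoissonSpec, poisson_spikes

    cfg = rc.core_config()
    if "events_file" in rc.input:
        events = read_spike_events(rc.base_dir / rc.input["events_file"])
        return events_to_raster(events, rc.steps, cfg.n_axons)
    if "poisson" in rc.input:
        spec = rc.input["poisson"]
        rates = np.broadcast_to(
            np.asarray(spec["rates"], dtype=float), (cfg.n_axons,)
        )
        return poisson_spikes(
            PoissonSpec(rates, rc.steps, seed=spec.get("seed", rc.seed))
        )
    return np.zeros((rc.steps, cfg.n_axons), dtype=bool)
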