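"""Idealized cycle model of the parallelized core.

The hardware processes P synapses per cycle (P memory banks, P
execution units), scans the axon array P flags at a time to skip zero
input, and fires N_n neurons in blocks of P.  Learning reads/writes the
synapse array in the row direction for post-then-pre events and in the
column direction for pre-then-post events; with the transposable bank
addressing a B-cell column window costs one parallel access, without it
every column window degenerates to B separate row reads.

The model is deliberately idealized — no pipeline stalls, no port
contention beyond the one-access-per-bank rule — so only orderings and
scalings (linearity in spike count, transposable <= row-only) are
meaningful, not absolute cycle counts.  No cycle-model setting feeds
back into functional simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import CoreConfig, StepTrace

__all__ = ["CycleReport", "count_cycles", "effective_throughput"]


@dataclass
class CycleReport:
    """Cycle totals per phase over a simulated trace."""

    cycles_scan: int
    cycles_integrate: int
    cycles_fire: int
    cycles_learn: int
    sops: int  # synapses actually read for integration
    steps: int

    @property
    def total_cycles(self) -> int:
        return self.cycles_scan + self.cycles_integrate + self.cycles_fire + self.cycles_learn


def count_cycles(
    trace: list[StepTrace], config: CoreConfig, transposable: bool = True
) -> CycleReport:
    """Cycle totals for a completed simulation trace.

    Per step: scan = ceil(N_a/P); integrate = ceil(N_f/P) per spiking
    axon; fire = ceil(N_n/P).  Learning: each post-then-pre event scans
    its row (ceil(N_f/P)); each pre-then-post event updates a column of
    r incident rows — ceil(r/P) accesses with transposable addressing,
    r row reads (P per column window) without.
    """
    cfg = config
    p = cfg.p
    scan_per_step = math.ceil(cfg.n_axons / p)
    row_cost = math.ceil(cfg.n_fanout / p)
    fire_per_step = math.ceil(cfg.n_neurons / p)

    cycles_scan = cycles_integrate = cycles_learn = sops = 0
    for st in trace:
        if st.spiking_axons < 0 or st.fired_neurons < 0:
            raise ValueError("inconsistent trace: negative event count")
        cycles_scan += scan_per_step
        cycles_integrate += st.spiking_axons * row_cost
        sops += st.spiking_axons * cfg.n_fanout
        cycles_learn += st.learn_row_events * row_cost
        for r in st.learn_col_rows:
            if transposable:
                cycles_learn += math.ceil(r / p)
            else:
                cycles_learn += math.ceil(r / p) * p  # p row reads per column window
    return CycleReport(
        cycles_scan=cycles_scan,
        cycles_integrate=cycles_integrate,
        cycles_fire=fire_per_step * len(trace),
        cycles_learn=cycles_learn,
        sops=sops,
        steps=len(trace),
    )


def effective_throughput(report: CycleReport, clock_hz: float) -> float:
    """Synaptic operations per second: sops * clock / total cycles."""
    if report.total_cycles <= 0:
        raise ValueError("cycle report has zero total cycles")
    return report.sops * clock_hz / report.total_cycles
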