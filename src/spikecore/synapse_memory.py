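"""Transposable banked synapse memory.

A digital neuromorphic core stores its synaptic weights in an R x C
crossbar (rows = axons, columns = fan-out slots).  Inference reads rows;
STDP learning must also write columns.  A conventional single-port SRAM
serves only one direction per cycle, so the logical matrix is split into
B banks and skewed: logical cell (x, y) lives in bank (x + y) mod B at
address floor((C*x + y) / B).  Under this skew any aligned window of B
consecutive cells — in either the row or the column direction — touches
each bank exactly once, so the whole window is serviced in a single
parallel access followed by a circular rotation of the B bank outputs
(a barrel shift in hardware).

This module models that store bit-exactly: integer weight codes, the
bank/address mapping, per-window address generation, and the output
rotation.  ``read_window``/``write_window`` go through the banked path
only; a plain 2-D array reconstruction is available via ``to_dense`` for
oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AccessWindow",
    "BankedSynapseMemory",
    "map_cell",
    "bank_addresses",
    "rotate_output",
    "read_window",
    "write_window",
]


@dataclass(frozen=True)
class AccessWindow:
    """An aligned window of B consecutive cells, row-wise or column-wise.

    Row windows start at (x, y) and cover (x, y..y+B-1); they require
    y to be a multiple of B.  Column windows cover (x..x+B-1, y) and
    require x to be a multiple of B.  Alignment keeps the address
    formula exact (a window never straddles a row boundary).
    """

    direction: Literal["row", "column"]
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.direction not in ("row", "column"):
            raise ValueError(f"direction must be 'row' or 'column', got {self.direction!r}")


def map_cell(x: int, y: int, C: int, B: int) -> tuple[int, int]:
    """Map logical cell (x, y) to its (bank, address) pair.

    The skewed placement: bank (x + y) mod B, address floor((C*x + y)/B).
    """
    if x < 0 or y < 0 or y >= C:
        raise IndexError(f"cell ({x}, {y}) out of range for C={C}")
    return (x + y) % B, (C * x + y) // B


def _check_window(win: AccessWindow, R: int, C: int, B: int) -> None:
    x, y = win.x, win.y
    if win.direction == "row":
        if y % B != 0:
            raise ValueError(f"row window start column {y} not aligned to B={B}")
        if not (0 <= x < R and 0 <= y and y + B <= C):
            raise ValueError(f"row window ({x}, {y}) out of bounds for {R}x{C}")
    else:
        if x % B != 0:
            raise ValueError(f"column window start row {x} not aligned to B={B}")
        if not (0 <= y < C and 0 <= x and x + B <= R):
            raise ValueError(f"column window ({x}, {y}) out of bounds for {R}x{C}")


def bank_addresses(win: AccessWindow, C: int, B: int) -> np.ndarray:
    """Per-bank addresses for an aligned window; index k is bank k.

    Bank k holds the window element whose logical offset within the
    window is (k - x - y) mod B, hence for row access
    Addr_k = floor((C*x + y + ((k - x - y) mod B)) / B) and for column
    access Addr_k = floor((C*(x + ((k - x - y) mod B)) + y) / B).
    Each bank is addressed exactly once.
    """
    k = np.arange(B)
    off = (k - win.x - win.y) % B
    if win.direction == "row":
        return (C * win.x + win.y + off) // B
    return (C * (win.x + off) + win.y) // B


def rotate_output(bank_outputs: Sequence, x: int, y: int, B: int) -> np.ndarray:
    """Rearrange the B bank outputs into logical window order.

    Output_l = bank_outputs[(l + x + y) mod B]; the same rotation serves
    row and column windows (the hardware barrel shifter).
    """
    out = np.asarray(bank_outputs)
    if out.shape[0] != B:
        raise ValueError(f"expected {B} bank outputs, got {out.shape[0]}")
    l = np.arange(B)
    return out[(l + x + y) % B]


class BankedSynapseMemory:
    """R x C signed weight codes remapped into B single-access banks.

    Parameters
    ----------
    R, C : int
        Logical row (axon) and column (fan-out slot) counts.  B must
        divide both.
    B : int
        Bank count; equals the core's parallelization factor P.
    weight_bits : int
        Bits per stored code; codes live in the signed range
        [-2**(weight_bits-1), 2**(weight_bits-1) - 1].
    """

    def __init__(self, R: int, C: int, B: int, weight_bits: int = 5):
        if B <= 0 or C % B != 0 or R % B != 0:
            raise ValueError(f"B={B} must be positive and divide R={R} and C={C}")
        if not 1 <= weight_bits <= 8:
            raise ValueError(f"weight_bits must be in 1..8, got {weight_bits}")
        self.R = R
        self.C = C
        self.B = B
        self.weight_bits = weight_bits
        self.banks = np.zeros((B, R * C // B), dtype=np.int64)

    @property
    def code_min(self) -> int:
        return -(1 << (self.weight_bits - 1))

    @property
    def code_max(self) -> int:
        return (1 << (self.weight_bits - 1)) - 1

    def _check_codes(self, values: np.ndarray) -> None:
        if values.min(initial=0) < self.code_min or values.max(initial=0) > self.code_max:
            raise ValueError(
                f"weight codes outside signed {self.weight_bits}-bit range "
                f"[{self.code_min}, {self.code_max}]"
            )

    @classmethod
    def from_dense(cls, W: np.ndarray, B: int, weight_bits: int = 5) -> "BankedSynapseMemory":
        """Load a logical integer matrix into banked form."""
        W = np.asarray(W, dtype=np.int64)
        R, C = W.shape
        mem = cls(R, C, B, weight_bits)
        mem._check_codes(W)
        xx, yy = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        mem.banks[(xx + yy) % B, (C * xx + yy) // B] = W
        return mem

    def to_dense(self) -> np.ndarray:
        """Reconstruct the logical R x C matrix (oracle/export path)."""
        xx, yy = np.meshgrid(np.arange(self.R), np.arange(self.C), indexing="ij")
        return self.banks[(xx + yy) % self.B, (self.C * xx + yy) // self.B].copy()

    # -- banked access path -------------------------------------------------

    def read_window(self, win: AccessWindow) -> np.ndarray:
        """Read B codes in logical order: one address per bank + rotation."""
        _check_window(win, self.R, self.C, self.B)
        addrs = bank_addresses(win, self.C, self.B)
        bank_out = self.banks[np.arange(self.B), addrs]
        return rotate_output(bank_out, win.x, win.y, self.B)

    def write_window(self, win: AccessWindow, values: Sequence) -> None:
        """Write B codes given in logical order (inverse rotation first)."""
        _check_window(win, self.R, self.C, self.B)
        values = np.asarray(values, dtype=np.int64)
        if values.shape[0] != self.B:
            raise ValueError(f"expected {self.B} values, got {values.shape[0]}")
        self._check_codes(values)
        addrs = bank_addresses(win, self.C, self.B)
        # bank k stores window element (k - x - y) mod B
        off = (np.arange(self.B) - win.x - win.y) % self.B
        self.banks[np.arange(self.B), addrs] = values[off]

    def read_row(self, x: int) -> np.ndarray:
        """Full logical row x via C/B consecutive aligned row windows."""
        parts = [self.read_window(AccessWindow("row", x, y)) for y in range(0, self.C, self.B)]
        return np.concatenate(parts)

    def write_row(self, x: int, values: Sequence) -> None:
        values = np.asarray(values, dtype=np.int64)
        if values.shape[0] != self.C:
            raise ValueError(f"expected {self.C} values, got {values.shape[0]}")
        for j, y in enumerate(range(0, self.C, self.B)):
            self.write_window(AccessWindow("row", x, y), values[j * self.B : (j + 1) * self.B])

    def read_column(self, y: int) -> np.ndarray:
        """Full logical column y via R/B consecutive aligned column windows."""
        parts = [self.read_window(AccessWindow("column", x, y)) for x in range(0, self.R, self.B)]
        return np.concatenate(parts)

    def write_column(self, y: int, values: Sequence) -> None:
        values = np.asarray(values, dtype=np.int64)
        if values.shape[0] != self.R:
            raise ValueError(f"expected {self.R} values, got {values.shape[0]}")
        for j, x in enumerate(range(0, self.R, self.B)):
            self.write_window(AccessWindow("column", x, y), values[j * self.B : (j + 1) * self.B])

    # -- text round trip ----------------------------------------------------

    def dump_banks(self, path) -> None:
        """Write the raw bank contents as delimited text (one row per bank)."""
        np.savetxt(
            path,
            self.banks,
            fmt="%d",
            delimiter="\t",
            header=f"R={self.R} C={self.C} B={self.B} weight_bits={self.weight_bits}",
        )

    @classmethod
    def load_banks(cls, path) -> "BankedSynapseMemory":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=") for kv in header.split())
        mem = cls(int(meta["R"]), int(meta["C"]), int(meta["B"]), int(meta["weight_bits"]))
        banks = np.loadtxt(path, dtype=np.int64, delimiter="\t", skiprows=1)
        mem.banks = banks.reshape(mem.banks.shape)
        return mem


def read_window(mem: BankedSynapseMemory, win: AccessWindow) -> np.ndarray:
    return mem.read_window(win)


def write_window(mem: BankedSynapseMemory, win: AccessWindow, values: Sequence) -> None:
    mem.write_window(win, values)
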