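"""Out-of-core execution of the update rules under a memory budget.

W and H stay fully resident (k is small); V is streamed through a bounded
working region in column blocks of width b_m during the H pass and row
blocks of height b_n during the W pass. Because each H column's update
depends only on that column of V (and all of W), and symmetrically for W
rows, blocking changes nothing but floating-point summation order.

As each block of H is updated, its row sums are accumulated into a running
k-length vector so the next W pass's denominator is ready without a second
sweep over H; the W pass accumulates column sums of W for the next H pass
the same way.

The memory footprint model counts, per H-pass block of width b:
resident W (n·k) + resident H (k·m) + the V block (n·b) + the product block
(n·b) + the updated k×b block + the k-length accumulator, all times the
element size; the W-pass model is symmetric over row blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .convergence import (
    ConvergenceReport,
    ConvergenceState,
    record_test,
    sample_assignment,
    should_test,
)
from .exceptions import ConfigError, DimensionError, FormatError
from .io import LabeledMatrix, _HEADER_STRUCT, _element_dtype
from .model import FactorPair, RunConfig, _h_step, _w_step, init_factors

__all__ = [
    "BlockPlan",
    "plan_blocks",
    "footprint_H",
    "footprint_W",
    "ArraySource",
    "BinaryFileSource",
    "update_H_blockwise",
    "update_W_blockwise",
    "fit_blockwise",
]


def footprint_H(n: int, m: int, k: int, b: int, element_size: int) -> int:
    """Bytes needed for an H pass with column blocks of width ``b``."""
    return element_size * (n * k + k * m + n * b + n * b + k * b + k)


def footprint_W(n: int, m: int, k: int, b: int, element_size: int) -> int:
    """Bytes needed for a W pass with row blocks of height ``b``."""
    return element_size * (n * k + k * m + b * m + b * m + b * k + k)


def _ranges(total: int, width: int) -> list[tuple[int, int]]:
    return [(s, min(s + width, total)) for s in range(0, total, width)]


@dataclass
class BlockPlan:
    """Column/row block widths and boundaries satisfying a byte budget."""

    b_m: int
    b_n: int
    col_blocks: list[tuple[int, int]]
    row_blocks: list[tuple[int, int]]
    budget_bytes: int
    element_size: int


def plan_blocks(
    n: int,
    m: int,
    k: int,
    element_size: int = 8,
    budget_bytes: int = 2 ** 60,
    b_m: Optional[int] = None,
    b_n: Optional[int] = None,
) -> BlockPlan:
    """Choose the largest block widths whose working set fits the budget.

    Explicit ``b_m``/``b_n`` overrides bypass the budget solve for that
    dimension. A budget too small even for single-column/row blocks raises
    :class:`ConfigError` reporting the minimum feasible budget.
    """
    if n < 1 or m < 1 or k < 1:
        raise ConfigError(f"dimensions must be positive, got n={n}, m={m}, k={k}")
    if budget_bytes <= 0:
        raise ConfigError("budget_bytes must be positive")
    # footprint(b) is linear in b: resident + b * per_unit.
    resident = n * k + k * m + k
    avail = budget_bytes // element_size - resident
    if b_m is None:
        b_m = min(m, avail // (2 * n + k)) if avail > 0 else 0
    if b_n is None:
        b_n = min(n, avail // (2 * m + k)) if avail > 0 else 0
    if b_m < 1 or b_n < 1:
        min_budget = element_size * (resident + max(2 * n + k, 2 * m + k))
        raise ConfigError(
            f"budget {budget_bytes} bytes too small: even single-column/row blocks "
            f"need {min_budget} bytes (resident W and H plus one unit block)"
        )
    if not (1 <= b_m <= m and 1 <= b_n <= n):
        raise ConfigError(f"block sizes out of range: b_m={b_m}, b_n={b_n}")
    return BlockPlan(
        b_m=int(b_m),
        b_n=int(b_n),
        col_blocks=_ranges(m, int(b_m)),
        row_blocks=_ranges(n, int(b_n)),
        budget_bytes=budget_bytes,
        element_size=element_size,
    )


class ArraySource:
    """Block access over an in-memory array; the trivial provider."""

    def __init__(self, values: np.ndarray):
        self.values = np.ascontiguousarray(values)
        self.peak_block_bytes = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def get_cols(self, j0: int, j1: int) -> np.ndarray:
        block = self.values[:, j0:j1]
        self.peak_block_bytes = max(self.peak_block_bytes, block.nbytes)
        return block

    def get_rows(self, i0: int, i1: int) -> np.ndarray:
        block = self.values[i0:i1, :]
        self.peak_block_bytes = max(self.peak_block_bytes, block.nbytes)
        return block


class BinaryFileSource:
    """Seek-and-read block access over a row-major little-endian binary file.

    Row blocks are one contiguous read; column blocks gather one row segment
    at a time. ``peak_block_bytes`` tracks the largest block materialized,
    so tests can verify the out-of-core path never exceeds its plan.
    """

    def __init__(
        self,
        path,
        n_rows: Optional[int] = None,
        n_cols: Optional[int] = None,
        precision: str = "double",
        header: bool = True,
    ):
        self.path = Path(path)
        self.dtype = _element_dtype(precision)
        self._offset = 0
        if header:
            with open(self.path, "rb") as fh:
                raw = fh.read(_HEADER_STRUCT.size)
            if len(raw) < _HEADER_STRUCT.size:
                raise FormatError(f"{path}: too short for an 8-byte dimension header")
            n_rows, n_cols = _HEADER_STRUCT.unpack(raw)
            self._offset = _HEADER_STRUCT.size
        elif n_rows is None or n_cols is None:
            raise ValueError("raw binary requires explicit n_rows and n_cols")
        self.n_rows, self.n_cols = int(n_rows), int(n_cols)
        expected = self._offset + self.n_rows * self.n_cols * self.dtype.itemsize
        actual = self.path.stat().st_size
        if actual != expected:
            raise FormatError(
                f"{path}: file is {actual} bytes, expected {expected} "
                f"for {self.n_rows}x{self.n_cols}"
            )
        self.peak_block_bytes = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_rows, self.n_cols

    def get_rows(self, i0: int, i1: int) -> np.ndarray:
        count = (i1 - i0) * self.n_cols
        try:
            with open(self.path, "rb") as fh:
                fh.seek(self._offset + i0 * self.n_cols * self.dtype.itemsize)
                block = np.fromfile(fh, dtype=self.dtype, count=count)
        except OSError as exc:
            raise FormatError(f"{self.path}: failed reading rows [{i0}, {i1}): {exc}")
        block = block.reshape(i1 - i0, self.n_cols).astype(np.float64)
        self.peak_block_bytes = max(self.peak_block_bytes, block.nbytes)
        return block

    def get_cols(self, j0: int, j1: int) -> np.ndarray:
        width = j1 - j0
        block = np.empty((self.n_rows, width))
        itemsize = self.dtype.itemsize
        try:
            with open(self.path, "rb") as fh:
                for i in range(self.n_rows):
                    fh.seek(self._offset + (i * self.n_cols + j0) * itemsize)
                    row = np.fromfile(fh, dtype=self.dtype, count=width)
                    if row.size != width:
                        raise FormatError(
                            f"{self.path}: short read in columns [{j0}, {j1}) at row {i}"
                        )
                    block[i] = row
        except OSError as exc:
            raise FormatError(f"{self.path}: failed reading cols [{j0}, {j1}): {exc}")
        self.peak_block_bytes = max(self.peak_block_bytes, block.nbytes)
        return block


def _as_source(V) -> Union[ArraySource, BinaryFileSource]:
    if isinstance(V, (ArraySource, BinaryFileSource)):
        return V
    if isinstance(V, LabeledMatrix):
        return ArraySource(V.values)
    if isinstance(V, (str, Path)):
        return BinaryFileSource(V)
    return ArraySource(np.asarray(V, dtype=float))


def update_H_blockwise(
    V_source, pair: FactorPair, plan: BlockPlan, epsilon: float
) -> tuple[np.ndarray, np.ndarray]:
    """One H pass over the plan's column blocks.

    W is fixed for the whole pass. Returns the updated H and the
    accumulated k-vector of its row sums.
    """
    source = _as_source(V_source)
    W, H = pair.W, pair.H
    k, m = H.shape
    if plan.col_blocks[-1][1] != m:
        raise DimensionError(f"plan covers {plan.col_blocks[-1][1]} columns, H has {m}")
    H_new = np.empty_like(H)
    row_sums = np.zeros(k, dtype=H.dtype)
    for j0, j1 in plan.col_blocks:
        V_block = source.get_cols(j0, j1)
        H_block = _h_step(V_block, W, H[:, j0:j1], pair.col_sums_W, epsilon)
        H_new[:, j0:j1] = H_block
        row_sums += H_block.sum(axis=1)
    return H_new, row_sums


def update_W_blockwise(
    V_source, pair: FactorPair, plan: BlockPlan, epsilon: float
) -> tuple[np.ndarray, np.ndarray]:
    """One W pass over the plan's row blocks, symmetric to the H pass.

    Uses the H produced by the preceding H pass and its accumulated row
    sums; returns the updated W and the accumulated column sums of W.
    """
    source = _as_source(V_source)
    W, H = pair.W, pair.H
    n, k = W.shape
    if plan.row_blocks[-1][1] != n:
        raise DimensionError(f"plan covers {plan.row_blocks[-1][1]} rows, W has {n}")
    W_new = np.empty_like(W)
    col_sums = np.zeros(k, dtype=W.dtype)
    for i0, i1 in plan.row_blocks:
        V_block = source.get_rows(i0, i1)
        W_block = _w_step(V_block, W[i0:i1, :], H, pair.row_sums_H, epsilon)
        W_new[i0:i1, :] = W_block
        col_sums += W_block.sum(axis=0)
    return W_new, col_sums


def _kl_blockwise(source, W, H, plan: BlockPlan) -> float:
    """KL divergence accumulated over column blocks (V never fully resident)."""
    total = 0.0
    for j0, j1 in plan.col_blocks:
        V_block = source.get_cols(j0, j1)
        WH = W @ H[:, j0:j1]
        mask = V_block > 0
        if np.any(WH[mask] == 0):
            return float("inf")
        total += float(np.sum(V_block[mask] * np.log(V_block[mask] / WH[mask])))
        total += float(WH.sum()) - float(V_block.sum())
    return total


def fit_blockwise(
    V, cfg: RunConfig, track_divergence: bool = False
) -> tuple[FactorPair, ConvergenceReport]:
    """Fit streaming V through the block plan implied by the config's budget.

    ``V`` may be a LabeledMatrix/array (sliced in memory) or a path /
    BinaryFileSource for true out-of-core access. Iteration and convergence
    semantics are identical to the in-memory fit; with a single-block plan
    the result is bit-identical to it.
    """
    source = _as_source(V)
    n, m = source.shape
    cfg.validate(n, m)
    budget = cfg.memory_budget_bytes if cfg.memory_budget_bytes is not None else 2 ** 60
    plan = plan_blocks(
        n,
        m,
        cfg.rank,
        element_size=cfg.dtype.itemsize,
        budget_bytes=budget,
        b_m=cfg.block_cols,
        b_n=cfg.block_rows,
    )
    pair = init_factors(n, m, cfg.rank, cfg.seed, cfg.precision)
    eps = cfg.dtype.type(cfg.epsilon)

    state = ConvergenceState()
    trace: Optional[list[float]] = [] if track_divergence else None
    stop_reason, iterations = "max_iters", cfg.max_iters
    converged = False
    for it in range(1, cfg.max_iters + 1):
        H_new, row_sums_H = update_H_blockwise(source, pair, plan, eps)
        pair.H = H_new
        pair.row_sums_H = row_sums_H
        W_new, col_sums_W = update_W_blockwise(source, pair, plan, eps)
        pair.W = W_new
        pair.col_sums_W = col_sums_W
        if trace is not None:
            trace.append(_kl_blockwise(source, pair.W, pair.H, plan))
        if should_test(it, cfg.test_period):
            _, converged = record_test(
                state, sample_assignment(pair.H), cfg.stability_threshold
            )
            if converged:
                stop_reason, iterations = "stable", it
                break
    report = ConvergenceReport(
        converged=converged,
        stop_reason=stop_reason,
        iterations_run=iterations,
        final_divergence=_kl_blockwise(source, pair.W, pair.H, plan),
        final_assignment=sample_assignment(pair.H),
        tests_run=state.tests_run,
        divergence_trace=trace,
    )
    return pair, report
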