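"""Data-parallel fitting with replicated factors.

Mirrors the multi-device scheme: V is partitioned among P workers — column
ranges for the H pass, row ranges for the W pass, both assigned at start —
while every worker keeps a full replica of W and H. After each update rule
one collective step restores coherence: the updated columns of H (rows of W)
are all-gathered in worker-rank order and the partial k-length sum vectors
are all-reduced by summation in ascending rank, so exactly two collectives
run per iteration.

The default backend executes the P workers in-process, which keeps the
synchronization structure (and its determinism) fully testable on one
machine; the collective contract is the pair of functions
:func:`sync_after_H` / :func:`sync_after_W`.

Workers initialize W and H from the same seed, so replicas agree at start
without a broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convergence import (
    ConvergenceReport,
    ConvergenceState,
    record_test,
    sample_assignment,
    should_test,
)
from .exceptions import ConfigError, SyncError
from .io import LabeledMatrix
from .model import FactorPair, RunConfig, _h_step, _w_step, init_factors, kl_divergence

__all__ = [
    "WorkerPartition",
    "make_partition",
    "sync_after_H",
    "sync_after_W",
    "fit_distributed",
]


@dataclass
class WorkerPartition:
    """One worker's share of the data and the global partition tables."""

    rank: int
    P: int
    my_cols: tuple[int, int]
    my_rows: tuple[int, int]
    all_col_ranges: list[tuple[int, int]]
    all_row_ranges: list[tuple[int, int]]


def _balanced_ranges(total: int, P: int) -> list[tuple[int, int]]:
    base, rem = divmod(total, P)
    ranges = []
    start = 0
    for r in range(P):
        size = base + (1 if r < rem else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def make_partition(n: int, m: int, P: int) -> list[WorkerPartition]:
    """Balanced contiguous split of columns and rows among P workers.

    Range sizes differ by at most one; deterministic for given (n, m, P).
    """
    if P < 1:
        raise ConfigError(f"worker count must be >= 1, got {P}")
    if P > min(n, m):
        raise ConfigError(f"worker count {P} exceeds min(n, m) = {min(n, m)}")
    col_ranges = _balanced_ranges(m, P)
    row_ranges = _balanced_ranges(n, P)
    return [
        WorkerPartition(
            rank=r,
            P=P,
            my_cols=col_ranges[r],
            my_rows=row_ranges[r],
            all_col_ranges=col_ranges,
            all_row_ranges=row_ranges,
        )
        for r in range(P)
    ]


def _gather_reduce(
    blocks: list[np.ndarray],
    partials: list[np.ndarray],
    axis: int,
) -> tuple[np.ndarray, np.ndarray]:
    """All-gather blocks along ``axis`` and all-reduce partial k-vectors.

    Contributions are concatenated / summed in ascending worker rank, fixing
    the floating-point order so distributed runs are reproducible.
    """
    if not blocks or len(blocks) != len(partials):
        raise SyncError(
            f"collective received {len(blocks)} blocks and {len(partials)} partial vectors"
        )
    if any(b is None for b in blocks) or any(p is None for p in partials):
        raise SyncError("missing worker contribution in collective step")
    full = np.concatenate(blocks, axis=axis)
    total = partials[0].copy()
    for p in partials[1:]:
        total += p
    return full, total


def sync_after_H(
    h_blocks: list[np.ndarray], partial_row_sums: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Collective after the H rule: gather column blocks, reduce row sums.

    Every worker receives the identical concatenated H (k x m) and the
    elementwise sum of the partial k-vectors.
    """
    return _gather_reduce(h_blocks, partial_row_sums, axis=1)


def sync_after_W(
    w_blocks: list[np.ndarray], partial_col_sums: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Collective after the W rule: gather row blocks, reduce column sums."""
    return _gather_reduce(w_blocks, partial_col_sums, axis=0)


@dataclass
class _Replica:
    """One worker's full copy of the factors and their sum vectors."""

    W: np.ndarray
    H: np.ndarray
    col_sums_W: np.ndarray
    row_sums_H: np.ndarray


def fit_distributed(V, cfg: RunConfig) -> tuple[FactorPair, ConvergenceReport]:
    """Fit with cfg.workers in-process data-parallel workers.

    Each iteration: every worker updates its own columns of H from its
    replica, one collective rebuilds the full H and global row sums on all
    replicas; then the same over its rows of W. Convergence is evaluated on
    the replicated H, identically on every worker. With P = 1 the result is
    bit-identical to the serial fit at the same seed.
    """
    values = V.values if isinstance(V, LabeledMatrix) else np.asarray(V, dtype=float)
    n, m = values.shape
    cfg.validate(n, m)
    P = cfg.workers
    parts = make_partition(n, m, P)
    values = np.ascontiguousarray(values, dtype=cfg.dtype)
    eps = cfg.dtype.type(cfg.epsilon)

    # Same seed on every worker -> identical replicas without a broadcast.
    replicas = []
    for _ in range(P):
        pair = init_factors(n, m, cfg.rank, cfg.seed, cfg.precision)
        replicas.append(
            _Replica(pair.W, pair.H, pair.W.sum(axis=0), pair.H.sum(axis=1))
        )

    state = ConvergenceState()
    stop_reason, iterations = "max_iters", cfg.max_iters
    converged = False
    collectives = 0
    for it in range(1, cfg.max_iters + 1):
        h_blocks, h_partials = [], []
        for part, rep in zip(parts, replicas):
            j0, j1 = part.my_cols
            H_block = _h_step(
                values[:, j0:j1], rep.W, rep.H[:, j0:j1], rep.col_sums_W, eps
            )
            h_blocks.append(H_block)
            h_partials.append(H_block.sum(axis=1))
        H_full, row_sums_H = sync_after_H(h_blocks, h_partials)
        collectives += 1
        for rep in replicas:
            rep.H = H_full.copy()
            rep.row_sums_H = row_sums_H.copy()

        w_blocks, w_partials = [], []
        for part, rep in zip(parts, replicas):
            i0, i1 = part.my_rows
            W_block = _w_step(
                values[i0:i1, :], rep.W[i0:i1, :], rep.H, rep.row_sums_H, eps
            )
            w_blocks.append(W_block)
            w_partials.append(W_block.sum(axis=0))
        W_full, col_sums_W = sync_after_W(w_blocks, w_partials)
        collectives += 1
        for rep in replicas:
            rep.W = W_full.copy()
            rep.col_sums_W = col_sums_W.copy()

        if should_test(it, cfg.test_period):
            # Replicated H is identical everywhere; rank 0's view stands for all.
            _, converged = record_test(
                state, sample_assignment(replicas[0].H), cfg.stability_threshold
            )
            if converged:
                stop_reason, iterations = "stable", it
                break

    rep0 = replicas[0]
    pair = FactorPair(rep0.W, rep0.H)
    report = ConvergenceReport(
        converged=converged,
        stop_reason=stop_reason,
        iterations_run=iterations,
        final_divergence=kl_divergence(values, rep0.W, rep0.H),
        final_assignment=sample_assignment(rep0.H),
        tests_run=state.tests_run,
        collective_steps=collectives,
    )
    return pair, report
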