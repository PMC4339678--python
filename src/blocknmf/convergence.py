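"""Sample/gene assignment and the stability-based stopping rule.

A sample (column of V) is assigned to the factor with its largest coefficient
in H; a gene (row of V) to the factor with its largest coefficient in W,
giving the biclustering view of the factorization. Convergence of a fit is
declared when the sample-assignment vector is unchanged over a required
number of consecutive periodic tests — the factorization is "stable" once
the induced classification stops moving, even though W and H themselves keep
drifting slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DimensionError, StateError

__all__ = [
    "ConvergenceState",
    "ConvergenceReport",
    "sample_assignment",
    "gene_assignment",
    "record_test",
    "should_test",
    "assignments_equivalent",
]


def sample_assignment(H: np.ndarray) -> np.ndarray:
    """Factor index of the maximum H coefficient for each sample (column).

    Ties break to the lowest factor index. Returns an int vector of length m.
    """
    H = np.asarray(H)
    if H.ndim != 2 or H.size == 0:
        raise DimensionError(f"H must be a non-empty k x m matrix, got shape {H.shape}")
    return np.argmax(H, axis=0)


def gene_assignment(W: np.ndarray) -> np.ndarray:
    """Factor index of the maximum W coefficient for each gene (row)."""
    W = np.asarray(W)
    if W.ndim != 2 or W.size == 0:
        raise DimensionError(f"W must be a non-empty n x k matrix, got shape {W.shape}")
    return np.argmax(W, axis=1)


def should_test(iteration: int, test_period: int) -> bool:
    """Whether a convergence test fires at this (1-based) iteration."""
    return iteration % test_period == 0


@dataclass
class ConvergenceState:
    """Mutable tracking state carried between periodic convergence tests."""

    last_assignment: Optional[np.ndarray] = None
    stable_count: int = 0
    tests_run: int = 0
    iterations_run: int = 0


def record_test(
    state: ConvergenceState, assignment: np.ndarray, threshold: int
) -> tuple[ConvergenceState, bool]:
    """Record one convergence test and report whether the run has converged.

    The stable counter increments when the assignment equals the previous
    test's assignment elementwise (exact label equality — factors persist
    within a run, so no permutation matching) and resets to zero otherwise.
    Converged once ``threshold`` consecutive stable comparisons accumulate.
    """
    assignment = np.asarray(assignment)
    if state.last_assignment is not None:
        if assignment.shape != state.last_assignment.shape:
            raise StateError(
                f"assignment length {assignment.shape} differs from previous "
                f"{state.last_assignment.shape}"
            )
        if np.array_equal(assignment, state.last_assignment):
            state.stable_count += 1
        else:
            state.stable_count = 0
    state.last_assignment = assignment.copy()
    state.tests_run += 1
    return state, state.stable_count >= threshold


@dataclass
class ConvergenceReport:
    """Outcome of a fit: why it stopped and where it ended."""

    converged: bool
    stop_reason: str  # "stable" or "max_iters"
    iterations_run: int
    final_divergence: float
    final_assignment: np.ndarray
    tests_run: int = 0
    divergence_trace: Optional[list[float]] = None
    collective_steps: int = 0


def assignments_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two assignment vectors agree up to a relabeling of factors.

    Used to compare a recovered classification against planted ground truth,
    where factor order is arbitrary: requires the label mapping a -> b to be
    a consistent bijection.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    forward: dict[int, int] = {}
    backward: dict[int, int] = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if forward.setdefault(x, y) != y or backward.setdefault(y, x) != x:
            return False
    return True
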