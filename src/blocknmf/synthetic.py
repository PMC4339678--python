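"""Synthetic gene-expression matrices with planted factor structure.

The generator emulates the shape of expression studies the factorization is
aimed at (thousands of gene rows, tens of sample columns, e.g. a 5000x38
two-class leukemia panel) at whatever scale a test needs. It plants a known
rank-k structure: every sample owns one factor, whose coefficient in its
column of H_true exceeds the off-factor coefficients by a fixed separation
ratio, so ``argmax`` over H_true recovers the planted labels by
construction. Optional half-normal noise (clipped at zero) perturbs
V = W_true @ H_true while preserving non-negativity.

What this does not emulate: real microarray intensity distributions,
gene-gene correlation, batch effects, or heavy-tailed platform noise — a
recovery result here shows the algorithm finds clean planted structure, not
that it resolves any particular real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .io import LabeledMatrix

__all__ = ["PlantedDataset", "make_planted", "make_worked_instances"]


@dataclass
class PlantedDataset:
    """A generated matrix plus its ground truth."""

    V: LabeledMatrix
    W_true: np.ndarray
    H_true: np.ndarray
    labels_true: np.ndarray
    noise_level: float
    seed: int


def make_planted(
    n: int,
    m: int,
    k: int,
    separation: float = 10.0,
    noise_level: float = 0.0,
    seed: int = 0,
) -> PlantedDataset:
    """Generate an n x m matrix with k planted factors.

    Parameters
    ----------
    separation : float > 1
        Ratio of a sample's owned-factor coefficient in H_true to its
        off-factor coefficients. Larger values give better-separated
        clusters; 10 is a clean, easily recoverable structure.
    noise_level : float >= 0
        Scale of additive half-normal noise relative to the mean signal.
        0 gives an exactly rank-k matrix.

    Samples cycle through factors (sample j owns factor j mod k), so every
    factor owns at least one sample whenever m >= k. Labels are formatted
    like expression exports: rows "gene0001", ..., columns "sample01", ....
    """
    if not (1 <= k <= min(n, m)):
        raise ConfigError(f"need 1 <= k <= min(n, m); got n={n}, m={m}, k={k}")
    if separation <= 1:
        raise ConfigError(f"separation must exceed 1, got {separation}")
    if noise_level < 0:
        raise ConfigError(f"noise_level must be >= 0, got {noise_level}")
    rng = np.random.default_rng(seed)

    labels = np.arange(m) % k
    base = rng.uniform(0.5, 1.5, size=m)
    H_true = np.tile(base, (k, 1))
    H_true[labels, np.arange(m)] *= separation
    W_true = rng.uniform(0.1, 1.0, size=(n, k))

    signal = W_true @ H_true
    values = signal
    if noise_level > 0:
        noise = np.abs(rng.normal(0.0, noise_level * signal.mean(), size=signal.shape))
        values = np.clip(signal + noise, 0.0, None)

    V = LabeledMatrix(
        values,
        row_labels=[f"gene{i + 1:04d}" for i in range(n)],
        col_labels=[f"sample{j + 1:02d}" for j in range(m)],
    )
    return PlantedDataset(
        V=V,
        W_true=W_true,
        H_true=H_true,
        labels_true=labels,
        noise_level=noise_level,
        seed=seed,
    )


def make_worked_instances() -> dict[str, dict[str, np.ndarray]]:
    """Tiny hand-checkable instances reused across the test suite.

    ``fixed_point``: V built exactly as W @ H, so one update leaves the
    factors unchanged. ``column_mean``: with W a column of ones, one H
    update lands on the column mean of V. ``oracle_2x2``: a small generic
    instance for comparing vectorized updates against loop-based evaluation.
    """
    W_fp = np.array([[1.0], [2.0]])
    H_fp = np.array([[3.0, 4.0]])
    return {
        "fixed_point": {"W": W_fp, "H": H_fp, "V": W_fp @ H_fp},
        "column_mean": {
            "W": np.array([[1.0], [1.0]]),
            "H": np.array([[1.0]]),
            "V": np.array([[2.0], [4.0]]),
            "expected_H": np.array([[3.0]]),
        },
        "oracle_2x2": {
            "V": np.array([[1.0, 2.0], [3.0, 4.0]]),
            "W": np.array([[1.0, 2.0], [3.0, 1.0]]),
            "H": np.array([[0.5, 0.5], [0.5, 0.5]]),
        },
    }
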