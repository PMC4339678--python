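"""Core NMF model: multiplicative updates, KL divergence, and the fit loop.

The model approximates a non-negative expression matrix V (n genes x m
samples) by a product W·H of two non-negative factors, W (n x k) holding
metagene coefficients per gene and H (k x m) holding metagene expression
levels per sample, with k << n, m. Fitting alternates the two multiplicative
update rules

    H_pj <- H_pj · [ Σ_i W_ip V_ij / (WH)_ij ] / Σ_r W_rp
    W_ip <- W_ip · [ Σ_j V_ij H_pj / (WH)_ij ] / Σ_t H_pt

which never increase the generalized Kullback–Leibler divergence

    D(V ‖ WH) = Σ_ij [ V_ij log(V_ij / (WH)_ij) − V_ij + (WH)_ij ].

A small epsilon (default 2**-52) is added inside both quotient denominators
to guard divisions; it preserves fixed points to machine precision.

The statsmodels-style surface is the :class:`NMF` model object whose
``fit()`` returns an :class:`NMFResults`. The H rule runs first in each
iteration: its pass accumulates the row sums of the updated H that the W
rule's denominator needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .convergence import (
    ConvergenceReport,
    ConvergenceState,
    gene_assignment,
    record_test,
    sample_assignment,
    should_test,
)
from .exceptions import ConfigError, DimensionError, DomainError
from .io import LabeledMatrix, write_text

__all__ = [
    "DEFAULT_EPSILON",
    "RunConfig",
    "FactorPair",
    "init_factors",
    "update_H",
    "update_W",
    "kl_divergence",
    "fit_full",
    "NMF",
    "NMFResults",
]

DEFAULT_EPSILON = 2.0 ** -52


@dataclass
class RunConfig:
    """Fit configuration.

    Defaults for the convergence controls follow the tool's documented
    example invocation: test every 10 iterations, require 40 consecutive
    stable tests, cap at 2000 iterations.
    """

    rank: int
    test_period: int = 10
    stability_threshold: int = 40
    max_iters: int = 2000
    seed: int = 0
    epsilon: float = DEFAULT_EPSILON
    precision: str = "double"
    memory_budget_bytes: Optional[int] = None
    block_cols: Optional[int] = None
    block_rows: Optional[int] = None
    workers: int = 1

    def validate(self, n: int, m: int) -> None:
        if self.rank < 1:
            raise ConfigError(f"rank must be >= 1, got {self.rank}")
        if self.rank > min(n, m):
            raise ConfigError(
                f"rank {self.rank} exceeds min(n, m) = {min(n, m)}"
            )
        for name in ("test_period", "stability_threshold", "max_iters", "workers"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.epsilon <= 0:
            raise ConfigError(f"epsilon must be > 0, got {self.epsilon}")
        if self.memory_budget_bytes is not None and self.memory_budget_bytes <= 0:
            raise ConfigError("memory_budget_bytes must be positive")
        if self.precision not in ("single", "double"):
            raise ConfigError(f"precision must be 'single' or 'double', got {self.precision!r}")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.float32 if self.precision == "single" else np.float64)


@dataclass
class FactorPair:
    """The factor matrices W (n x k), H (k x m) and their cached sum vectors.

    ``col_sums_W[p] = Σ_r W_rp`` feeds the H rule's denominator and
    ``row_sums_H[p] = Σ_t H_pt`` the W rule's; the fit loops keep them in
    step with the factors after every update.
    """

    W: np.ndarray
    H: np.ndarray
    col_sums_W: np.ndarray = field(default=None)  # type: ignore[assignment]
    row_sums_H: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise DimensionError(
                f"inconsistent factor shapes W {self.W.shape}, H {self.H.shape}"
            )
        if self.col_sums_W is None or self.row_sums_H is None:
            self.refresh_sums()

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    def refresh_sums(self) -> None:
        self.col_sums_W = self.W.sum(axis=0)
        self.row_sums_H = self.H.sum(axis=1)


def init_factors(n: int, m: int, k: int, seed: int, precision: str = "double") -> FactorPair:
    """Seeded random initialization: i.i.d. uniform draws on (0, 1].

    Identical (n, m, k, seed) gives bit-identical factors; a strictly
    positive start avoids absorbing zeros in the multiplicative updates.
    """
    if n < 1 or m < 1 or k < 1:
        raise ConfigError(f"dimensions must be positive, got n={n}, m={m}, k={k}")
    if k > min(n, m):
        raise ConfigError(f"rank {k} exceeds min(n, m) = {min(n, m)}")
    rng = np.random.default_rng(seed)
    dtype = np.float32 if precision == "single" else np.float64
    # 1 - U([0,1)) lies in (0, 1]: no exact zeros.
    W = (1.0 - rng.random((n, k))).astype(dtype)
    H = (1.0 - rng.random((k, m))).astype(dtype)
    return FactorPair(W, H)


def _check_triple(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    if V.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise DimensionError(
            f"shapes not conformable: V {V.shape}, W {W.shape}, H {H.shape}"
        )
    for name, M in (("V", V), ("W", W), ("H", H)):
        if (M < 0).any():
            raise DomainError(f"{name} contains negative entries")


def _h_step(V_block, W, H_block, col_sums_W, epsilon):
    """One H update restricted to a column block; the workhorse kernel."""
    ratio = V_block / (W @ H_block + epsilon)
    return H_block * ((W.T @ ratio) / (col_sums_W + epsilon)[:, None])


def _w_step(V_block, W_block, H, row_sums_H, epsilon):
    """One W update restricted to a row block."""
    ratio = V_block / (W_block @ H + epsilon)
    return W_block * ((ratio @ H.T) / (row_sums_H + epsilon)[None, :])


def update_H(V, W, H, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Apply the H multiplicative rule once; inputs are left unmodified."""
    V, W, H = np.asarray(V), np.asarray(W), np.asarray(H)
    _check_triple(V, W, H)
    return _h_step(V, W, H, W.sum(axis=0), epsilon)


def update_W(V, W, H, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Apply the W multiplicative rule once; inputs are left unmodified."""
    V, W, H = np.asarray(V), np.asarray(W), np.asarray(H)
    _check_triple(V, W, H)
    return _w_step(V, W, H, H.sum(axis=1), epsilon)


def kl_divergence(V, W, H) -> float:
    """Generalized KL divergence D(V ‖ WH); +inf where WH = 0 under V > 0.

    Zero-valued V entries contribute only their (WH) term (0·log 0 ≡ 0).
    """
    V, W, H = np.asarray(V), np.asarray(W), np.asarray(H)
    if V.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise DimensionError(
            f"shapes not conformable: V {V.shape}, W {W.shape}, H {H.shape}"
        )
    WH = W @ H
    mask = V > 0
    if np.any(WH[mask] == 0):
        return float("inf")
    log_term = float(np.sum(V[mask] * np.log(V[mask] / WH[mask])))
    return log_term - float(V.sum()) + float(WH.sum())


def _fit_serial(
    V: np.ndarray,
    cfg: RunConfig,
    assignment_fn: Callable[[np.ndarray], np.ndarray] = sample_assignment,
    track_divergence: bool = False,
) -> tuple[FactorPair, ConvergenceReport]:
    """The in-memory alternating loop shared by ``NMF.fit`` and ``fit_full``."""
    n, m = V.shape
    cfg.validate(n, m)
    V = np.ascontiguousarray(V, dtype=cfg.dtype)
    pair = init_factors(n, m, cfg.rank, cfg.seed, cfg.precision)
    W, H = pair.W, pair.H
    col_sums_W = W.sum(axis=0)
    eps = cfg.dtype.type(cfg.epsilon)

    state = ConvergenceState()
    trace: Optional[list[float]] = [] if track_divergence else None
    stop_reason, iterations = "max_iters", cfg.max_iters
    converged = False
    for it in range(1, cfg.max_iters + 1):
        H = _h_step(V, W, H, col_sums_W, eps)
        row_sums_H = H.sum(axis=1)
        W = _w_step(V, W, H, row_sums_H, eps)
        col_sums_W = W.sum(axis=0)
        if trace is not None:
            trace.append(kl_divergence(V, W, H))
        if should_test(it, cfg.test_period):
            _, converged = record_test(state, assignment_fn(H), cfg.stability_threshold)
            if converged:
                stop_reason, iterations = "stable", it
                break
    pair = FactorPair(W, H)
    report = ConvergenceReport(
        converged=converged,
        stop_reason=stop_reason,
        iterations_run=iterations,
        final_divergence=kl_divergence(V, W, H),
        final_assignment=sample_assignment(H),
        tests_run=state.tests_run,
        divergence_trace=trace,
    )
    return pair, report


def fit_full(V, cfg: RunConfig, track_divergence: bool = False):
    """Fit with everything in memory; returns ``(FactorPair, ConvergenceReport)``."""
    values = V.values if isinstance(V, LabeledMatrix) else np.asarray(V, dtype=float)
    if (values < 0).any():
        raise DomainError("non-negative input required")
    return _fit_serial(values, cfg, track_divergence=track_divergence)


class NMF:
    """Non-negative matrix factorization model for an expression matrix.

    Parameters
    ----------
    data : array-like or LabeledMatrix
        Non-negative matrix V, genes in rows and samples in columns.
    rank : int
        Number of factors (metagenes) k; must not exceed min(n, m).
    row_labels, col_labels : optional sequences of str
        Gene and sample names, propagated to the fitted factors.

    Examples
    --------
    >>> from blocknmf import NMF
    >>> from blocknmf.synthetic import make_planted
    >>> ds = make_planted(n=50, m=12, k=3, seed=0)
    >>> res = NMF(ds.V, rank=3).fit(seed=0)
    >>> res.W.shape, res.H.shape
    ((50, 3), (3, 12))
    """

    def __init__(self, data, rank: int, row_labels=None, col_labels=None):
        if isinstance(data, LabeledMatrix):
            mat = data
            if row_labels is not None or col_labels is not None:
                mat = LabeledMatrix(data.values, row_labels, col_labels)
        else:
            mat = LabeledMatrix(np.asarray(data, dtype=float), row_labels, col_labels)
        self.data = mat
        self.rank = int(rank)
        n, m = mat.shape
        if not 1 <= self.rank <= min(n, m):
            raise ConfigError(f"rank must lie in [1, {min(n, m)}], got {rank}")

    @classmethod
    def from_dataframe(cls, df, rank: int) -> "NMF":
        """Build from a pandas DataFrame (index = genes, columns = samples)."""
        return cls(
            np.asarray(df, dtype=float),
            rank,
            row_labels=[str(x) for x in df.index],
            col_labels=[str(x) for x in df.columns],
        )

    @classmethod
    def from_file(cls, path, rank: int, **read_kwargs) -> "NMF":
        """Build from a tab-separated text matrix on disk."""
        from .io import read_text

        return cls(read_text(path, **read_kwargs), rank)

    def fit(
        self,
        seed: int = 0,
        test_period: int = 10,
        stability_threshold: int = 40,
        max_iters: int = 2000,
        epsilon: float = DEFAULT_EPSILON,
        precision: str = "double",
        memory_budget_bytes: Optional[int] = None,
        block_cols: Optional[int] = None,
        block_rows: Optional[int] = None,
        workers: int = 1,
        track_divergence: bool = False,
    ) -> "NMFResults":
        """Run the alternating updates until stable assignments or the cap.

        With a memory budget (or explicit block sizes) V is streamed in
        column/row blocks; with ``workers`` > 1 the data-parallel scheme
        partitions V among in-process workers with replicated factors.
        """
        cfg = RunConfig(
            rank=self.rank,
            test_period=test_period,
            stability_threshold=stability_threshold,
            max_iters=max_iters,
            seed=seed,
            epsilon=epsilon,
            precision=precision,
            memory_budget_bytes=memory_budget_bytes,
            block_cols=block_cols,
            block_rows=block_rows,
            workers=workers,
        )
        if workers > 1:
            from .parallel import fit_distributed

            pair, report = fit_distributed(self.data, cfg)
        elif memory_budget_bytes is not None or block_cols is not None or block_rows is not None:
            from .blocking import fit_blockwise

            pair, report = fit_blockwise(self.data, cfg, track_divergence=track_divergence)
        else:
            pair, report = _fit_serial(
                self.data.values, cfg, track_divergence=track_divergence
            )
        return NMFResults(self, cfg, pair, report)


class NMFResults:
    """Fitted factors plus convergence diagnostics.

    Attributes
    ----------
    W, H : ndarray
        The fitted factor matrices.
    report : ConvergenceReport
        Stop reason, iteration count, final divergence, final assignment.
    """

    def __init__(self, model: NMF, config: RunConfig, pair: FactorPair, report: ConvergenceReport):
        self.model = model
        self.config = config
        self.factors = pair
        self.report = report

    @property
    def W(self) -> np.ndarray:
        return self.factors.W

    @property
    def H(self) -> np.ndarray:
        return self.factors.H

    @property
    def divergence(self) -> float:
        return self.report.final_divergence

    def sample_assignment(self) -> np.ndarray:
        return sample_assignment(self.H)

    def gene_assignment(self) -> np.ndarray:
        return gene_assignment(self.W)

    def factor_labels(self) -> list[str]:
        return [f"f{p}" for p in range(self.factors.rank)]

    def W_matrix(self) -> LabeledMatrix:
        """W as a LabeledMatrix: gene rows, factor columns."""
        return LabeledMatrix(
            self.W, row_labels=self.model.data.row_labels, col_labels=self.factor_labels()
        )

    def H_matrix(self) -> LabeledMatrix:
        """H as a LabeledMatrix: factor rows, sample columns."""
        return LabeledMatrix(
            self.H, row_labels=self.factor_labels(), col_labels=self.model.data.col_labels
        )

    def save(self, w_path, h_path) -> None:
        """Write W and H as tab-separated text with labels."""
        write_text(self.W_matrix(), w_path)
        write_text(self.H_matrix(), h_path)

    def summary(self) -> str:
        """A plain-text summary table of the fit."""
        n, m = self.model.data.shape
        assign = self.report.final_assignment
        counts = np.bincount(assign, minlength=self.factors.rank)
        sizes = "  ".join(f"f{p}:{c}" for p, c in enumerate(counts))
        lines = [
            "     Non-negative Matrix Factorization Results",
            "=" * 54,
            f"Genes (rows):        {n:>8}    Rank k:       {self.factors.rank:>8}",
            f"Samples (cols):      {m:>8}    Seed:         {self.config.seed:>8}",
            f"Iterations run:      {self.report.iterations_run:>8}    Converged:    {str(self.report.converged):>8}",
            f"Stop reason:         {self.report.stop_reason:>8}    Tests run:    {self.report.tests_run:>8}",
            f"Final KL divergence: {self.report.final_divergence:>12.6g}",
            f"Samples per factor:  {sizes}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<NMFResults k={self.factors.rank} iters={self.report.iterations_run} "
            f"stop={self.report.stop_reason} D={self.report.final_divergence:.4g}>"
        )
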