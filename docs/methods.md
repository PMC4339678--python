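# Methods

## Model

blocknmf factorizes a non-negative expression matrix V (n genes × m
samples) as V ≈ W·H with W ∈ R₊^{n×k}, H ∈ R₊^{k×m} and k ≪ n, m. The
objective is the generalized Kullback–Leibler divergence
D(V‖WH) = Σ (V log(V/WH) − V + WH), with 0·log 0 ≡ 0 and D = +∞ whenever
WH = 0 under a positive V entry. Fitting alternates the classical
multiplicative updates for this objective (H rule then W rule each
iteration); each rule rescales its factor elementwise by a ratio of sums
and provably never increases D. The assumptions are those of KL-NMF
generally: entries of V are non-negative intensities on a common scale, and
a parts-based rank-k description is meaningful. Nothing is normalized for
the user; scaling columns of V rescales H accordingly.

## Numerical choices

- **Epsilon guard.** Both quotient denominators — the elementwise
  V/(WH) and the k-length sum vectors — receive an additive epsilon,
  default 2⁻⁵² (double-precision machine epsilon). This makes the updates
  total functions without measurably moving fixed points: when V = WH
  exactly, one full iteration changes the factors by < 1e-10 relative.
- **Initialization.** W and H start as i.i.d. uniform draws on (0, 1] from
  `numpy.random.default_rng(seed)`; the open lower bound avoids absorbing
  zeros (a zero entry can never leave zero under multiplicative updates).
  Identical (n, m, k, seed) gives bit-identical starts, so whole runs are
  deterministic.
- **Update order.** H first, then W. The H pass accumulates the row sums of
  the updated H that the W rule's denominator needs, so each iteration
  needs no extra sweep over the factors.
- **Precision.** Double precision is the default and what the equivalence
  guarantees are stated at; single precision is selectable
  (`precision="single"`) for halved memory footprints.
- **Ties.** Sample and gene assignments break argmax ties to the lowest
  factor index — deterministic and order-independent.
- **H orientation.** H is stored in its logical k×m orientation (no
  transposed storage; that is a kernel-reuse device with no benefit here).

## Convergence rule

Every `test_period` (j) iterations the sample assignment argmaxₚ H_pj is
computed and compared elementwise with the previous test's assignment.
Equality increments a stable counter, any difference resets it to zero; the
run stops "stable" once `stability_threshold` (t) consecutive stable
comparisons accumulate, else "max_iters" at the cap (i). Defaults are
j=10, t=40, i=2000 — the tool's documented example invocation. The
comparison is exact label equality, not permutation-invariant matching:
factors persist within a run, so a label flip between tests is a real
change of solution, and matching under permutation would mask it.
(Permutation-invariant comparison is provided separately, as
`assignments_equivalent`, for judging recovery against planted truth where
factor order *is* arbitrary.)

## Out-of-core execution

W and H (and their two k-length sum vectors) always stay resident; V is
streamed. Because each column of the H update depends only on that column
of V (and all of W), and symmetrically for W rows, processing V in
contiguous column blocks of width b_m (H pass) and row blocks of height
b_n (W pass) is mathematically identical to the in-memory rules — only
floating-point summation order differs, and a single-block plan is
bit-identical.

Block widths come from an explicit footprint model: an H pass with width-b
blocks needs `element_size · (n·k + k·m + n·b + n·b + k·b + k)` bytes
(resident W and H, the V block, the WH product block, the updated k×b
block, the accumulator); the W pass is symmetric over rows. `plan_blocks`
picks the largest b_m, b_n whose footprint fits `memory_budget_bytes`
(closed form; the linearity in b makes this exact) and errors with the
minimum feasible budget when even unit blocks do not fit. Blocks are
contiguous equal-width ranges with a short tail. Two block providers exist:
in-memory slicing, and seek-and-read over the row-major binary file (row
blocks are one contiguous read; column blocks gather a row segment at a
time). There is no prefetching or read/compute overlap — this is a
correctness-first artifact and overlap would add nondeterminism.

## Data-parallel execution

With P workers, V is partitioned once at start in both dimensions
(balanced contiguous ranges, sizes differing by at most one): worker r owns
a column range for the H pass and a row range for the W pass, while W and H
are fully replicated on every worker. After each update rule one collective
step restores coherence: the updated columns of H (rows of W) are
all-gathered in ascending worker rank and the partial k-length sum vectors
all-reduced by summation in the same fixed order — exactly two collectives
per iteration, and the fixed order makes distributed runs reproducible.
All workers initialize from the same seed, so replicas agree at start
without a broadcast. Convergence is evaluated on the replicated H,
identically everywhere.

The backend executes the P workers in-process (each with genuinely
separate replica arrays), which makes the synchronization structure fully
testable on one machine; the collective contract is the function pair
`sync_after_H` / `sync_after_W`, behind which a message-passing transport
could be slotted. Workers process their portion in one piece; combining
per-worker blocking with distribution is not implemented.

With P = 1 the result is bit-identical to the serial fit; for P > 1 it
matches within summation-order noise (measured ~1e-14 relative after 100
iterations, asserted at 1e-8).

## Synthetic data

`make_planted(n, m, k, separation, noise_level, seed)` emulates an
expression study with a planted rank-k structure at whatever scale a test
needs (the shapes mirror common study geometry — thousands of gene rows,
tens of sample columns). Sample j owns factor j mod k; in its column of
H_true the owned coefficient is `separation` (default 10) times the
off-factor coefficients, which are a shared per-column draw from
U(0.5, 1.5); W_true is U(0.1, 1.0). Noise, when requested, is additive
half-normal with scale `noise_level` × mean signal, clipped at zero, so V
stays non-negative without rejection sampling. Row/column labels are
formatted like expression exports ("gene0001", "sample01") so labeled I/O
paths get exercised.

What the generator does **not** emulate: real microarray intensity
distributions, gene–gene correlation, batch structure, or heavy-tailed
platform noise. Passing recovery tests therefore demonstrates that the
algorithm and its execution paths are correct and recover clean planted
structure — not that any particular real dataset resolves at a given rank.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
finish in seconds while still exercising every path: update rules are
checked against triple-nested-loop oracle evaluation on random instances up
to 10×10 with k ≤ 4; divergence monotonicity over 440 iterations on 20
random 100×40 rank-4 problems; blockwise and 4-worker fits against the
in-memory fit on 200×120 with k=5 and a budget forcing ≥ 4 blocks per
dimension (100 iterations, agreement required at 1e-8 elementwise);
planted-label recovery on 500×40 with k=3 and separation 10 across 20
seeds under the default stopping rule.

## Limitations

- Dense matrices only; no sparse storage, no missing values.
- KL objective only; no Frobenius variant, no sparseness or smoothness
  constraints.
- Single restart per call: consensus/cophenetic model selection across
  restarts is left to the caller (loop over seeds and compare
  `sample_assignment` vectors).
- The in-process parallel backend demonstrates and tests the
  synchronization scheme but does not itself use multiple cores.
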