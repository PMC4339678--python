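# blocknmf

Out-of-core non-negative matrix factorization (NMF) for gene-expression
matrices, on the CPU. It factorizes a non-negative matrix **V** (n genes ×
m samples) as **V ≈ W·H**, with **W** (n × k) holding the coefficients of
each gene in k *metagenes* and **H** (k × m) the expression level of each
metagene in each sample. Dominant-coefficient membership in **W** and **H**
gives a biclustering view of the data, and assigning each sample to its
largest H coefficient classifies samples by metagene.

The package is for analysts factorizing expression matrices that may be
larger than the memory they want to spend: **V** can be streamed from disk
in column/row blocks under an explicit byte budget, and the fit can be run
data-parallel across several workers with replicated factors — both paths
are exactly equivalent (up to floating-point summation order) to the plain
in-memory algorithm.

## Model and algorithm

Fitting minimizes the generalized Kullback–Leibler divergence

D(V‖WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ/(WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ]

by alternating the multiplicative update rules

- H_pj ← H_pj · [ Σᵢ W_ip Vᵢⱼ/(WH)ᵢⱼ ] / Σ_r W_rp
- W_ip ← W_ip · [ Σⱼ Vᵢⱼ H_pj/(WH)ᵢⱼ ] / Σ_t H_pt

which preserve non-negativity and never increase D. The H rule runs first
each iteration; as its column blocks are updated, their row sums are
accumulated into the k-length vector the W rule's denominator needs.
Convergence is declared when the sample-to-factor assignment
(argmaxₚ H_pj per sample) is unchanged over a required number of
consecutive periodic tests; otherwise the run stops at the iteration cap.

## Worked example

```python
from blocknmf import NMF, assignments_equivalent
from blocknmf.synthetic import make_planted

ds = make_planted(n=50, m=12, k=3, separation=10.0, noise_level=0.0, seed=0)
res = NMF(ds.V, rank=3).fit(seed=0)   # j=10, t=40, i=2000 defaults
print(res.summary())
print("recovered planted labels:",
      assignments_equivalent(res.sample_assignment(), ds.labels_true))
```

prints

```
     Non-negative Matrix Factorization Results
======================================================
Genes (rows):              50    Rank k:              3
Samples (cols):            12    Seed:                0
Iterations run:           430    Converged:        True
Stop reason:           stable    Tests run:          43
Final KL divergence:   0.00281631
Samples per factor:  f0:4  f1:4  f2:4
======================================================
recovered planted labels: True
```

The assignment stabilized early and stayed unchanged for 40 consecutive
tests (taken every 10 iterations), so the run stopped "stable" at
iteration 430; the three planted sample clusters of four samples each were
recovered exactly, and the residual divergence on this noise-free rank-3
matrix is near zero. Streaming and parallel variants are keyword arguments
of the same `fit()`: `memory_budget_bytes=100_000` streams V in blocks that
fit the budget, `workers=4` runs the data-parallel scheme.

The same analysis from a shell:

```bash
blocknmf generate -n 50 -m 12 -k 3 --outdir data
blocknmf run data/planted.txt -k 3 -j 10 -t 40 -i 2000
# -> data/planted.txt_W.txt, data/planted.txt_H.txt, data/planted.txt_run.json
```

Input is tab-separated text (optional gene-row / sample-column labels) or
row-major IEEE little-endian binary (`--binary`; 8-byte dimension header by
default, `--raw-binary` for headerless files).

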